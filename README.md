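# fusbbbd

Quantitative safety assessment for focused-ultrasound (FUS) blood–brain-barrier
disruption (BBBD), for researchers running microbubble-mediated BBB-opening
studies who need the downstream number-crunching — not the hardware control —
as tested, reusable code.

When a focused transducer drives circulating microbubbles inside brain
vasculature, three questions decide whether a sonication protocol is safe and
effective, and this package answers each from its standard measurement:

1. **What kind of cavitation occurred?** From passive cavitation detector
   (PCD) burst recordings, the package computes Parseval-scaled burst spectra
   and reads out harmonic (n·f_c), sub/ultra-harmonic (n·f_c/2, odd n) and
   broadband band levels, normalizes them to a no-microbubble baseline, and
   integrates the baseline excess over the sonication into three cumulative
   doses: SCDh (stable cavitation, harmonic), SCDu (stable, sub/ultra-harmonic)
   and ICD (inertial cavitation, broadband).
2. **How permeable did the barrier become?** From DCE-MRI ROI curves, the
   Patlak model C_t(t) = K^trans ∫₀ᵗ C_p dτ + v_p C_p(t) is linearized and fit
   by ordinary least squares in Patlak coordinates
   (y = C_t/C_p against x = ∫C_p/C_p), giving the volume transfer constant
   K^trans (min⁻¹) as slope and the plasma volume fraction v_p as intercept.
   T1 is estimated from a variable-TR saturation-recovery series
   S(TR) = S₀(1 − e^(−TR/T1)), and concentration follows from the linear
   relaxivity relation C = (1/T1_post − 1/T1_pre)/r₁. Relative signal
   enhancement 100·(post − pre)/pre is the quick-look alternative.
3. **What did the tissue do about it?** From a gene × sample FPKM matrix over
   a post-sonication time course, the package filters all-zero genes, applies
   log2(FPKM+1) quantile normalization, calls differentially expressed genes
   per timepoint against sham by an independent t-test with a fold-change +
   p-value rule, tests gene sets by the one-sided hypergeometric
   over-representation test with Benjamini–Hochberg adjustment, scores
   pan/M1/M2 microglial and pan/A1/A2 astrocyte marker panels on log2
   fold-changes, and validates expression calls against qPCR via the 2^−ΔΔCq
   method and Pearson correlation.

Every input has a seeded synthetic generator (`fusbbbd.simulate`) with known
ground truth, so the whole pipeline runs and is verified at desk scale without
any animal data.

## Worked example

Simulate one ROI-averaged DCE study at a ground-truth K^trans of 0.06 min⁻¹
with 3 % noise, fit the Patlak model, and compute cavitation doses for a
stable and an inertial sonication:

```python
import fusbbbd.simulate as sim
from fusbbbd.dce import patlak_fit
from fusbbbd.cavitation import compute_doses

ds = sim.gen_dce_dataset(sim.DceSimConfig(true_ktrans=0.06, true_vp=0.01, seed=42))
print(patlak_fit(ds.ct_noisy, ds.cp).summary())

cfg = sim.CavSimConfig(sampling_rate=10e6, burst_length=0.002, duration=20, seed=42)
for regime in ("stable", "inertial"):
    base, treat, _ = sim.gen_pcd_dataset(cfg, regime)
    doses, _ = compute_doses(treat, base)
    print(f"{regime:9s} SCDh={doses.scd_h:9.1f}  SCDu={doses.scd_u:8.1f}  ICD={doses.icd:6.2f}")
```

prints

```
Patlak model fit
================
n points used               100
Ktrans (min^-1)         0.05911  (se 0.00038)
v_p                     0.01539  (se 0.0033)
R-squared                0.9960

stable    SCDh=  27276.9  SCDu=     0.4  ICD=  0.09
inertial  SCDh=  27277.9  SCDu=  6551.4  ICD= 76.07
```

The fitted K^trans (0.059 min⁻¹) recovers the 0.06 min⁻¹ truth to within the
noise; R² near 1 says the Patlak line describes the curve. The dose table
shows the safety-relevant signature: harmonic emission (SCDh) dominates in
both regimes, while sub/ultra-harmonic dose (SCDu) and broadband inertial
dose (ICD) — the damage-associated channels — appear only in the inertial
regime.

The same objects are reachable from a shell via the `fusbbbd` CLI
(`fusbbbd simulate …`, `fusbbbd cavdose …`, `fusbbbd dce fit …`,
`fusbbbd rnaseq degs …`, `fusbbbd glial score …`, `fusbbbd qpcr ddcq …`).

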