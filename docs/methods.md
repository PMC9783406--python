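# Methods

This note records the models implemented in `fusbbbd`, the assumptions and
defaults behind them, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## Cavitation dose metrics

**Signal model.** A sonication is a train of bursts (default geometry:
10 ms bursts at 1 Hz pulse-repetition frequency for 120 s — a 1 % duty
cycle — at a fundamental of f_c = 1.1 MHz, sampled at 20 MHz). Recordings
are represented burst-segmented: the analysis never touches the inter-burst
gaps, so the canonical in-memory form is an (n_bursts × window) array;
flat 1-D traces with onset metadata are accepted and sliced identically.

**Spectrum.** Each burst window is tapered (Hann by default; rectangular
available, and used wherever a test needs exact Parseval identities) and
transformed to a one-sided amplitude spectrum scaled so that the sum of
squared amplitudes equals the mean squared signal. For a tapered spectrum
the normalization uses the taper RMS, which preserves broadband power in
expectation; tonal peak heights then carry the usual coherent-gain bias,
which cancels exactly in baseline normalization because baseline and
treatment share the taper.

**Band readout.** Harmonic level is the root-sum-square over orders
n = 1..4 of the peak amplitude within ±50 kHz of n·f_c; sub/ultra-harmonic
level likewise at n·f_c/2 for n = 1, 3, 5, 7 (the first of these is the
subharmonic; the dose metric pools them). Broadband level is the
root-sum-square of all bins in the 0.3–5 MHz analysis band (the passband
of a 2.25 MHz-centred detector) after excluding ±150 kHz around every
tonal centre. The 50/150 kHz halfwidths are wide relative to the spectral
leakage of a ≥2 ms windowed burst and narrow relative to the 550 kHz
half-spacing of the tonal comb; all are configurable.

**Doses.** Treatment band levels are divided by the time-mean of the
corresponding baseline (no-microbubble) band level; ratios below 1 are
floored at 1 so that emission at baseline level contributes zero excess.
Each dose is the trapezoidal time-integral of (ratio − 1) over burst time:
SCDh from the harmonic band, SCDu from the sub/ultra-harmonic band, ICD
from the broadband band, in dimensionless-excess·seconds. The integrand is
a config switch: `rms_excess` (default) integrates the amplitude-ratio
excess; `power_excess` squares the ratio first. Division (not subtraction)
keeps doses unit-free and detector-gain-independent; the floor guarantees
nonnegative doses.

**Desk-scale problem size.** The regime-ordering checks in the test suite
run at 10 MHz sampling, 2 ms bursts and 20–30 s sonications. This keeps
the spectral structure (bin spacing ≤ 500 Hz, bands resolved by two orders
of magnitude) while making a 20-seed sweep take seconds; the full 120 s /
20 MHz geometry runs through the identical code path.

## DCE-MRI permeability

**Patlak model.** C_t(t) = K^trans·∫₀ᵗC_p dτ + v_p·C_p(t). The plasma
integral is the cumulative trapezoid with the convention C_p(0) = 0 (bolus
arrives after the first sample); the fit is closed-form OLS on the Patlak
coordinates y = C_t/C_p, x = ∫C_p/C_p, restricted to an optional time
window, with the t = 0 point excluded (C_p = 0 there by convention). The
forward generator uses the same trapezoid operator, so noiseless curves
are recovered exactly (tested at 1e-8 relative error). A v_p = 0
restricted variant is available. K^trans is reported in min⁻¹; expressing
time in seconds rescales it by exactly 60 (tested).

**Arterial input function.** A bi-exponential bolus decay,
C_p(t) = Σ aᵢ·e^(−mᵢt), defaults a = (5, 1) mM, m = (3, 0.05) min⁻¹ —
a fast redistribution phase and a slow clearance phase. The study this
package serves reports no AIF, so these are plausible small-animal bolus
kinetics; they live in `DceSimConfig`, not in code.

**T1 and concentration.** T1 comes from a variable-TR saturation-recovery
series S(TR) = S₀(1 − e^(−TR/T1)), fitted by bounded least squares with a
deterministic initialization (S₀ ← max signal, T1 ← median TR; tolerance
1e-10, bounded iterations). Concentration uses the linear relaxivity
relation C = (1/T1_post − 1/T1_pre)/r₁ with defaults r₁ = 3.5
L·mmol⁻¹·s⁻¹ and T1_pre = 1.9 s — typical gadolinium-chelate and rodent
grey-matter values at high field; both are assumptions exposed in config,
as the source study states neither.

**Noise model.** Additive Gaussian noise on the tissue curve at 3 % of its
peak (and the same fractional noise on the dynamic signal). The ground
truths used throughout are the two group means the pipeline is designed to
distinguish: 0.06 min⁻¹ (high-pressure condition) and 0.02 min⁻¹
(low-pressure), with v_p = 0.01. At these settings the per-curve estimate
scatters a few percent and the 200-curve mean recovers truth well within
10 %; the threefold group ratio is reproduced at 3.0 ± 0.3.

**Enhancement.** 100·(post − pre)/pre on T1-weighted ROI signals, with a
pair generator applying independent 3 % multiplicative noise to both
signals at true enhancements of 56.6 % and 93.2 % (the two pressure
conditions). The ratio estimator's multiplicative-noise bias at 3 % is
≈0.1 percentage point, far inside the group SDs used as tolerances.

## Expression time course

**Pipeline.** Genes with FPKM = 0 in every sample are dropped; values
become log2(FPKM+1) and are quantile-normalized globally across all
samples (after normalization every sample's sorted vector equals the
row-rank means; ties get the average-rank value). Differential expression
is an independent two-sample t-test per gene, one comparison per
(condition, timepoint) against the sham group, with
log2FC = mean(treatment) − mean(sham) on the normalized scale. A gene is a
DEG when |log2FC| exceeds the threshold and p < 0.05 in at least one
comparison. Two threshold modes exist because the field prints both
conventions: `log2fc_gt2` (|log2FC| > 2; default) and `fc_gt2`
(fold-change > 2, i.e. |log2FC| > 1). DEG p-values are deliberately not
multiplicity-corrected (matching common practice for exploratory
time-course screens); Benjamini–Hochberg FDR is applied only to gene-set
enrichment, which is a one-sided hypergeometric over-representation test
against user-supplied GMT collections.

**Welch vs pooled.** The default test is Welch's (unequal variances) —
the safer choice when group variances differ. At n = 2 per group Welch is
known to be conservative: its measured type-I rate under the generator's
null is ≈0.025 at nominal 0.05, because the Welch–Satterthwaite degrees of
freedom are estimated from two observations per group. The pooled-variance
option is exact for the generator's equal-variance normal null (measured
0.042–0.053 through the full pipeline), so the calibration property in the
test suite is asserted on the pooled variant, alongside an assertion that
Welch is conservative and never anticonservative. Neither test has much
power at n = 2; the suite asserts ≥80 % recall of strongly induced genes
rather than perfection.

**Quantile normalization and ties.** Exact idempotence (re-normalizing
changes nothing, to 1e-12) holds for tie-free data and is tested as such.
When ties are present, average-rank assignment perturbs the order
statistics, so repeated renormalization is a fixed-point iteration rather
than an identity; with real filtered FPKM data the residual motion is
negligible but not exactly zero. This is a property of tie-averaged
quantile normalization itself, not of this implementation.

**Generator.** log2 FPKM per gene is Normal(μ_g, σ) with per-gene centres
μ_g ~ Normal(3, 2) (a realistic FPKM dynamic range), replicate dispersion
σ = 0.3 on the log2 scale, n = 2 replicates per group (the design this
package mirrors), conditions sham / low / high over timepoints 1, 6, 12,
24, 48 h. Sham and low draw from the null; high applies a per-timepoint
induction profile (default 0.5 → 3.5 log2 units, monotone in time,
emulating an accumulating inflammatory program) to a random 2 % of genes,
plus panel-specific effects to marker-panel genes. 5 % of genes are
all-zero to exercise filtering. A negative-binomial count layer is
deliberately omitted: the pipeline starts from FPKM, and a log-normal
FPKM model is sufficient for everything downstream of that entry point.
What passing tests therefore show is that the *computations* are correct
and calibrated under a clean log-normal null — not that the thresholds
would have the same operating characteristics on count-level noise,
batch effects or correlated genes, none of which the generator emulates.

## Glial polarization scoring

A marker panel is scored as the unweighted mean log2FC of its genes
present in the matrix at each timepoint (missing genes are excluded and
reported as coverage). Dominance of subtype A over B across a window
requires score_A − score_B ≥ min_margin (default 0.25 log2 units) at
*every* timepoint in the window; otherwise the call is `unpolarized`,
which is a first-class scientific outcome — bulk microglial data
frequently activates pan markers without resolving an M1/M2 split, and the
generator's defaults reproduce exactly that (pan up, M1 ≈ M2) while
driving an A2-dominant astrocyte program over 12–48 h. The shipped panel
TSV contains the marker symbols printed in the figures of the source
literature (e.g. Emp1, Tgm1, Tm4sf1, CD14 for A2); it is a starting point,
and real analyses should substitute the full published reactivity panels.

## qPCR quantification

ΔCq = Cq(target) − Cq(reference) per sample; ΔΔCq = group-mean ΔCq minus
calibrator-group-mean ΔCq; fold = E^(−ΔΔCq) with amplification efficiency
E fixed at 2.0 (the 100 %-efficiency assumption of the 2^−ΔΔCq method; an
efficiency-corrected base is exposed but off by default). The calibrator
is a group mean, so fold(calibrator) = 1 exactly for every gene. Because
group means of ΔCq are means of logs, folds are geometric-mean ratios —
the correct behaviour for ratio data. Concordance with RNA-seq uses
Pearson correlation on log2(fold) vs log2(FPKM+1) means by default
(linear-scale option available). The Cq generator writes
Cq = offset − log_E(expression) + noise, so the pipeline inverts it
exactly at zero noise and within ~1 % at a realistic 0.1-cycle noise sd.

## Numerical and degenerate-input conventions

- Patlak R² for an exactly constant y (e.g. C_t = v_p·C_p) is defined as
  1 for a perfect fit rather than 1 − ε/ε.
- Zero within-group variance in both groups makes the t-test undefined:
  the gene is flagged `zero_variance` and never called.
- A baseline band with zero mean power, a burst extending past the trace,
  overlapping tonal bands, non-monotone time grids, C_p ≤ 0 inside the fit
  window, a missing reference gene, and an empty calibrator group are all
  hard errors; per-ROI failures inside a batch are flagged rows instead.
- Printed DEG percentages use half-even rounding to two decimals.
- All generators are pure functions of (config, seed); NumPy's
  `default_rng` supplies the stream.

## Problem sizes

The test suite and the acceptance script are sized for a laptop-class
single core: 200 simulated ROI curves per permeability group, 100
enhancement pairs per pressure group, 20-seed cavitation sweeps at the
desk-scale sonication geometry, 200-dataset null calibrations, and
500-draw enrichment uniformity checks. The full suite runs in well under a
minute; the acceptance script in a few seconds.

## Known limitations

- ROI-averaged curves only; no voxelwise K^trans mapping or image-domain
  synthesis (NIfTI), and no AIF estimation from images.
- The Patlak model ignores backflux; at high permeability or long
  acquisitions an extended-Tofts model would be needed.
- Cavitation doses are relative (baseline-normalized), not calibrated to
  absolute acoustic pressure; detector frequency response is not modelled.
- The expression generator's independence and log-normality assumptions
  understate real RNA-seq structure (counts, correlation, batch), so
  calibration results transfer to real data only qualitatively.
- Marker-panel lists are partial (figure-printed symbols), and panel
  scores are unweighted means; no single-cell deconvolution is attempted.
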