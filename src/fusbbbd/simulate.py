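"""Synthetic-data generators for every pipeline input, with known ground
truth and seeded randomness.

Each generator is a pure function of its config (including the seed):
calling it twice with the same config yields bit-identical data.  The
defaults encode the study conditions the pipeline is meant to analyse —
1.1 MHz sonication in 10 ms bursts at 1 Hz PRF sampled at 20 MHz, a
bi-exponential arterial input function with Patlak tissue kinetics, and a
two-pressure five-timepoint expression time course with n = 2 replicates
per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cavitation import PCDRecording
from .dce import ConcentrationCurve, TRSeries, signal_from_concentration
from .qpcr import CqTable
from .transcriptomics import ExpressionMatrix

__all__ = [
    "CavSimConfig",
    "DceSimConfig",
    "DceDataset",
    "ExprSimConfig",
    "gen_pcd_dataset",
    "gen_dce_dataset",
    "gen_expression_dataset",
    "gen_qpcr_dataset",
    "gen_enhancement_dataset",
]


# --------------------------------------------------------------------------
# PCD recordings


@dataclass
class CavSimConfig:
    """Sonication geometry and emission amplitudes for PCD synthesis.

    Amplitudes are arbitrary voltage units; the i-th entry of
    ``harmonic_amplitudes`` drives the tone at (i+1)*fc, and of
    ``ultraharmonic_amplitudes`` the tone at (2i+1)*fc/2.  In the stable
    regime burst noise stays at ``baseline_noise_sd``; the inertial regime
    raises it to ``broadband_noise_sd`` and switches the ultraharmonic
    tones on.
    """

    sampling_rate: float = 20e6       # Hz
    fundamental_fc: float = 1.1e6     # Hz
    burst_length: float = 0.010       # s
    prf: float = 1.0                  # Hz
    duration: float = 120.0           # s
    harmonic_amplitudes: tuple = (1.0, 0.5, 0.3, 0.2)
    ultraharmonic_amplitudes: tuple = (0.2, 0.15, 0.1, 0.08)
    broadband_noise_sd: float = 0.05
    baseline_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burst_length * self.prf > 1.0 + 1e-12:
            raise ValueError("burst_length * prf must be <= 1 (duty cycle)")
        if any(a < 0 for a in self.harmonic_amplitudes + self.ultraharmonic_amplitudes):
            raise ValueError("amplitudes must be nonnegative")
        if self.baseline_noise_sd < 0 or self.broadband_noise_sd < 0:
            raise ValueError("noise sds must be nonnegative")

    @property
    def n_bursts(self) -> int:
        return int(math.floor(self.duration * self.prf))

    @property
    def duty_cycle(self) -> float:
        return self.burst_length * self.prf


def gen_pcd_dataset(
    config: CavSimConfig, regime: str, harmonic_orders: tuple | None = None
) -> tuple[PCDRecording, PCDRecording, dict]:
    """Baseline (no microbubble) and treatment PCD recordings plus truth.

    The baseline recording contains Gaussian noise only.  Treatment bursts
    carry harmonic tones at n*fc; in the ``inertial`` regime additionally
    ultraharmonic tones at n*fc/2 (odd n) and a broadband noise floor at
    ``broadband_noise_sd``.  Tone phases are drawn per burst.
    """
    if regime not in ("stable", "inertial"):
        raise ValueError(f"unknown regime {regime!r}; expected stable|inertial")
    if harmonic_orders is None:
        harmonic_orders = tuple(range(1, len(config.harmonic_amplitudes) + 1))
    if len(config.harmonic_amplitudes) < len(harmonic_orders):
        raise ValueError("harmonic_amplitudes shorter than requested orders")

    rng = np.random.default_rng(config.seed)
    n_bursts = config.n_bursts
    win = int(round(config.burst_length * config.sampling_rate))
    onsets = np.arange(n_bursts, dtype=float) / config.prf
    t = np.arange(win) / config.sampling_rate

    tones = [
        (n * config.fundamental_fc, a)
        for n, a in zip(harmonic_orders, config.harmonic_amplitudes)
    ]
    uh_tones = []
    if regime == "inertial":
        uh_orders = range(1, 2 * len(config.ultraharmonic_amplitudes), 2)
        uh_tones = [
            (n * config.fundamental_fc / 2.0, a)
            for n, a in zip(uh_orders, config.ultraharmonic_amplitudes)
        ]
    burst_sd = (
        config.broadband_noise_sd if regime == "inertial" else config.baseline_noise_sd
    )

    baseline = rng.normal(0.0, config.baseline_noise_sd, size=(n_bursts, win))
    treatment = rng.normal(0.0, burst_sd, size=(n_bursts, win))
    for i in range(n_bursts):
        for f, a in tones + uh_tones:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            treatment[i] += a * np.sin(2.0 * np.pi * f * t + phase)

    def _rec(samples: np.ndarray) -> PCDRecording:
        return PCDRecording(
            samples=samples,
            sampling_rate=config.sampling_rate,
            burst_onsets=onsets,
            burst_length=config.burst_length,
            fundamental_fc=config.fundamental_fc,
        )

    truth = {
        "harmonic": dict(zip(harmonic_orders, config.harmonic_amplitudes)),
        "ultraharmonic": {f / (config.fundamental_fc / 2.0): a for f, a in uh_tones},
        "burst_noise_sd": burst_sd,
        "baseline_noise_sd": config.baseline_noise_sd,
    }
    return _rec(baseline), _rec(treatment), truth


# --------------------------------------------------------------------------
# DCE-MRI


@dataclass
class DceSimConfig:
    """Ground truth and acquisition settings for one ROI-averaged DCE study.

    The arterial input function is a bi-exponential bolus decay,
    C_p(t) = sum_i a_i * exp(-m_i * t) for t > 0 with C_p(0) = 0;
    tissue kinetics follow the Patlak forward model at
    (``true_ktrans``, ``true_vp``).  ``noise_sd`` is the additive noise sd
    expressed as a fraction of the peak value of the noised curve.
    """

    true_ktrans: float = 0.06     # min^-1
    true_vp: float = 0.01         # fraction
    aif_amplitudes: tuple = (5.0, 1.0)   # mM
    aif_rates: tuple = (3.0, 0.05)       # min^-1
    t1_baseline: float = 1.9      # s
    relaxivity_r1: float = 3.5    # L mmol^-1 s^-1
    tr_list: tuple = (0.1, 0.3, 0.6, 1.0, 1.8, 3.0, 5.0)  # s
    tr_s0: float = 1000.0         # a.u.
    dyn_tr: float = 0.05          # s, dynamic series repetition time
    sample_times: tuple = tuple(np.round(np.arange(0.0, 10.01, 0.1), 10))  # min
    noise_sd: float = 0.03        # fraction of peak
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_ktrans < 0:
            raise ValueError("true_ktrans must be >= 0")
        if not 0 <= self.true_vp < 1:
            raise ValueError("true_vp must be in [0, 1)")
        st = np.asarray(self.sample_times, dtype=float)
        if st[0] != 0 or np.any(np.diff(st) <= 0):
            raise ValueError("sample_times must increase strictly from 0")


@dataclass
class DceDataset:
    tr_series: TRSeries
    cp: ConcentrationCurve
    ct: ConcentrationCurve          # noiseless tissue concentration
    ct_noisy: ConcentrationCurve    # tissue concentration + additive noise
    signal_noisy: np.ndarray        # dynamic tissue signal with the same noise model
    config: DceSimConfig


def gen_dce_dataset(config: DceSimConfig) -> DceDataset:
    """Variable-TR series, plasma curve, tissue curve, and noisy outputs.

    The noiseless C_t obeys the Patlak forward model exactly under the
    cumulative-trapezoid plasma integral used by the fitting routine.
    """
    from scipy.integrate import cumulative_trapezoid

    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.sample_times, dtype=float)
    cp = np.zeros_like(t)
    pos = t > 0
    for a, m in zip(config.aif_amplitudes, config.aif_rates):
        cp[pos] += a * np.exp(-m * t[pos])
    integral = cumulative_trapezoid(cp, t, initial=0.0)
    ct = config.true_ktrans * integral + config.true_vp * cp

    sd_ct = config.noise_sd * (np.max(ct) if np.max(ct) > 0 else 1.0)
    ct_noisy = ct + rng.normal(0.0, sd_ct, size=ct.shape)

    signal = signal_from_concentration(
        ct,
        t1_pre=config.t1_baseline,
        r1=config.relaxivity_r1,
        tr=config.dyn_tr,
        s0=config.tr_s0,
    )
    sd_sig = config.noise_sd * np.max(signal)
    signal_noisy = signal + rng.normal(0.0, sd_sig, size=signal.shape)

    tr = np.asarray(config.tr_list, dtype=float)
    tr_signals = config.tr_s0 * (1.0 - np.exp(-tr / config.t1_baseline))
    return DceDataset(
        tr_series=TRSeries(tr_values=tr, signals=tr_signals),
        cp=ConcentrationCurve(times=t, values=cp),
        ct=ConcentrationCurve(times=t, values=ct),
        ct_noisy=ConcentrationCurve(times=t, values=ct_noisy),
        signal_noisy=signal_noisy,
        config=config,
    )


def gen_enhancement_dataset(
    true_percent: float, noise_sd: float = 0.03, n: int = 100, seed: int = 0,
    pre_level: float = 100.0,
) -> pd.DataFrame:
    """Noisy pre/post ROI signal pairs at a known true enhancement.

    Both signals carry independent multiplicative Gaussian noise of
    relative sd ``noise_sd``.  Returns columns pre, post.
    """
    rng = np.random.default_rng(seed)
    pre = pre_level * (1.0 + rng.normal(0.0, noise_sd, size=n))
    post = pre_level * (1.0 + true_percent / 100.0) * (
        1.0 + rng.normal(0.0, noise_sd, size=n)
    )
    return pd.DataFrame({"pre": pre, "post": post})


# --------------------------------------------------------------------------
# Expression matrix


@dataclass
class ExprSimConfig:
    """Two-pressure, five-timepoint expression time course with ground truth.

    Sham and the low-pressure condition draw from the per-gene null
    distribution; the high-pressure condition adds
    ``induction_log2fc_profile`` to a random ``induced_gene_fraction`` of
    genes and ``panel_effects`` to panel-assigned genes, per timepoint.
    FPKM is log-normal: log2 FPKM ~ Normal(gene mean, ``dispersion``).
    """

    n_genes: int = 2000
    conditions: tuple = ("sham", "low", "high")
    timepoints: tuple = (1.0, 6.0, 12.0, 24.0, 48.0)   # h
    replicates_per_group: int = 2
    induced_gene_fraction: float = 0.02
    induction_log2fc_profile: tuple = (0.5, 1.5, 2.5, 3.0, 3.5)
    panel_assignments: dict = field(default_factory=dict)   # panel -> gene indices
    panel_effects: dict = field(default_factory=dict)       # panel -> per-tp log2FC
    zero_gene_fraction: float = 0.05
    dispersion: float = 0.3       # sd of log2 FPKM across replicates
    baseline_mean: float = 3.0    # mean of per-gene log2 FPKM centers
    baseline_sd: float = 2.0
    gene_ids: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.induced_gene_fraction <= 1:
            raise ValueError("induced_gene_fraction must be in [0, 1]")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2 (t-test undefined)")
        if len(self.induction_log2fc_profile) != len(self.timepoints):
            raise ValueError("induction profile length must match timepoints")
        for panel, idx in self.panel_assignments.items():
            if any(i >= self.n_genes for i in idx):
                raise ValueError(f"panel {panel!r} gene index out of range")
            if panel in self.panel_effects and len(
                self.panel_effects[panel]
            ) != len(self.timepoints):
                raise ValueError(f"panel {panel!r} effect length must match timepoints")
        if self.gene_ids is not None and len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length must equal n_genes")


def gen_expression_dataset(
    config: ExprSimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """FPKM matrix + design table + per-gene truth.

    Truth columns: gene, induced, panel, zero.  The induced set excludes
    panel and all-zero genes so every effect has a single source.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = (
        list(config.gene_ids)
        if config.gene_ids is not None
        else [f"gene{i:05d}" for i in range(n)]
    )
    tp_index = {tp: j for j, tp in enumerate(config.timepoints)}

    panel_of = {}
    for panel, idx in config.panel_assignments.items():
        for i in idx:
            panel_of[i] = panel
    reserved = set(panel_of)

    n_zero = int(round(config.zero_gene_fraction * n))
    free = np.array([i for i in range(n) if i not in reserved])
    zero_idx = set(rng.choice(free, size=n_zero, replace=False)) if n_zero else set()
    free2 = np.array([i for i in free if i not in zero_idx])
    n_induced = int(round(config.induced_gene_fraction * n))
    induced_idx = (
        set(rng.choice(free2, size=n_induced, replace=False)) if n_induced else set()
    )

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    samples, columns = [], []
    design_rows = []
    for cond in config.conditions:
        tps = (0.0,) if cond == "sham" else config.timepoints
        for tp in tps:
            for rep in range(1, config.replicates_per_group + 1):
                sid = f"{cond}_t{tp:g}_r{rep}"
                x = rng.normal(mu, config.dispersion)
                if cond == "high" and tp in tp_index:
                    j = tp_index[tp]
                    for i in induced_idx:
                        x[i] += config.induction_log2fc_profile[j]
                    for i, panel in panel_of.items():
                        eff = config.panel_effects.get(panel)
                        if eff is not None:
                            x[i] += eff[j]
                fpkm = np.power(2.0, x)
                fpkm[list(zero_idx)] = 0.0
                samples.append(fpkm)
                columns.append(sid)
                design_rows.append(
                    {
                        "sample_id": sid,
                        "condition": cond,
                        "timepoint_h": tp,
                        "replicate": rep,
                    }
                )

    fpkm_df = pd.DataFrame(
        np.column_stack(samples), index=pd.Index(genes, name="gene"), columns=columns
    )
    design = pd.DataFrame(design_rows).set_index("sample_id")
    truth = pd.DataFrame(
        {
            "gene": genes,
            "induced": [i in induced_idx for i in range(n)],
            "panel": [panel_of.get(i, "") for i in range(n)],
            "zero": [i in zero_idx for i in range(n)],
        }
    )
    return ExpressionMatrix(fpkm=fpkm_df, design=design), truth


# --------------------------------------------------------------------------
# qPCR


def gen_qpcr_dataset(
    expr: ExpressionMatrix,
    reference_gene: str,
    genes: list | None = None,
    efficiency: float = 2.0,
    cq_offset: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CqTable:
    """Back-compute quantification cycles from expression values.

    Cq = cq_offset - log_eff(expression) + Normal(0, noise_sd) per
    (sample, gene), so that the ddCq pipeline inverts exactly at zero
    noise.  The reference gene must have nonzero expression everywhere.
    """
    if reference_gene not in expr.fpkm.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from matrix")
    if (expr.fpkm.loc[reference_gene] <= 0).any():
        raise ValueError(f"reference gene {reference_gene!r} has zero expression")
    if genes is None:
        genes = [g for g in expr.fpkm.index if g != reference_gene][:8]
    for g in genes:
        if g not in expr.fpkm.index:
            raise ValueError(f"gene {g!r} absent from matrix")
        if (expr.fpkm.loc[g] <= 0).any():
            raise ValueError(f"gene {g!r} has zero expression in some sample")

    rng = np.random.default_rng(seed)
    log_base = np.log2(efficiency)
    rows = []
    for g in list(genes) + [reference_gene]:
        vals = expr.fpkm.loc[g]
        for sid, v in vals.items():
            cq = cq_offset - np.log2(v) / log_base
            if noise_sd > 0:
                cq += rng.normal(0.0, noise_sd)
            rows.append({"sample_id": sid, "gene": g, "cq": float(cq)})
    data = pd.DataFrame(rows)
    if (data["cq"] <= 0).any():
        raise ValueError("cq_offset too small: nonpositive Cq generated")
    return CqTable(data=data, design=expr.design, reference_gene=reference_gene)
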