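"""Relative qPCR quantification by the 2^-ddCq method and validation of
fold changes against RNA-seq expression.

dCq  = Cq(target) - Cq(reference gene) per sample;
ddCq = mean dCq(group) - mean dCq(calibrator group);
fold = 2^-ddCq  (assumes 100% amplification efficiency; an
efficiency-corrected base is exposed but off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CqTable",
    "delta_delta_cq",
    "correlate_with_rnaseq",
]


@dataclass
class CqTable:
    """Long-format quantification-cycle table.

    ``data``: DataFrame with columns sample_id, gene, cq.
    ``design``: DataFrame indexed by sample_id with columns condition,
    timepoint_h, replicate.  ``reference_gene`` must be measured (cq > 0)
    in every sample.
    """

    data: pd.DataFrame
    design: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"sample_id", "gene", "cq"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"Cq table needs columns {sorted(required)}")
        if (self.data["cq"] <= 0).any():
            raise ValueError("Cq values must be positive")
        samples = set(self.data["sample_id"])
        ref = self.data[self.data["gene"] == self.reference_gene]
        if set(ref["sample_id"]) != samples:
            raise ValueError(
                f"reference gene {self.reference_gene!r} not measured in every sample"
            )
        missing = samples - set(self.design.index)
        if missing:
            raise ValueError(f"design table missing samples: {sorted(missing)}")


def _group_key(design: pd.DataFrame) -> pd.Series:
    return design["condition"].astype(str) + "@" + design["timepoint_h"].astype(str)


def delta_delta_cq(
    table: CqTable, calibrator: str, efficiency: float = 2.0
) -> pd.DataFrame:
    """Relative expression per (gene, condition, timepoint) group.

    ``calibrator`` names the condition whose group mean dCq anchors the
    comparison (e.g. "sham").  Returns columns gene, condition,
    timepoint_h, ddcq, fold, fold_sd_rep (replicate spread propagated as
    efficiency^-sd(dCq)-style log-scale sd of the per-replicate folds).
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency base must exceed 1")
    data = table.data
    ref = (
        data[data["gene"] == table.reference_gene]
        .set_index("sample_id")["cq"]
        .rename("cq_ref")
    )
    targets = data[data["gene"] != table.reference_gene].copy()
    if targets.empty:
        raise ValueError("no target genes in the Cq table")
    targets["dcq"] = targets["cq"] - targets["sample_id"].map(ref)
    design = table.design
    targets["condition"] = targets["sample_id"].map(design["condition"])
    targets["timepoint_h"] = targets["sample_id"].map(design["timepoint_h"])

    cal = targets[targets["condition"] == calibrator]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator!r} is empty")
    cal_mean = cal.groupby("gene")["dcq"].mean()

    rows = []
    for (gene, cond, tp), grp in targets.groupby(
        ["gene", "condition", "timepoint_h"], sort=True
    ):
        ddcq = float(grp["dcq"].mean() - cal_mean[gene])
        rep_folds = efficiency ** -(grp["dcq"] - cal_mean[gene])
        rows.append(
            {
                "gene": gene,
                "condition": cond,
                "timepoint_h": tp,
                "ddcq": ddcq,
                "fold": float(efficiency**-ddcq),
                "fold_sd_rep": float(rep_folds.std(ddof=1))
                if len(rep_folds) > 1
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def correlate_with_rnaseq(
    folds: np.ndarray,
    fpkm_means: np.ndarray,
    log_scale: bool = True,
) -> tuple[float, float, int]:
    """Pearson correlation between qPCR fold changes and matched RNA-seq
    expression.

    By default both vectors are log2-transformed (folds -> log2(fold),
    FPKM -> log2(FPKM + 1)); ``log_scale=False`` correlates raw values.
    Returns (r, two-sided p, n).
    """
    folds = np.asarray(folds, dtype=float)
    fpkm_means = np.asarray(fpkm_means, dtype=float)
    if folds.shape != fpkm_means.shape or folds.ndim != 1:
        raise ValueError("inputs must be matched 1-D vectors")
    n = folds.size
    if n < 3:
        raise ValueError("need at least 3 matched pairs")
    x = np.log2(folds) if log_scale else folds
    y = np.log2(fpkm_means + 1.0) if log_scale else fpkm_means
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(n)
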