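"""Bulk RNA-seq time-course analysis starting from a gene x sample FPKM
matrix: zero-expression filtering, log2(FPKM+1) quantile normalization,
per-timepoint differential expression against a sham control, DEG calling
under a fold-change + p-value rule, and gene-set over-representation.

The experimental design emulated here is a sonication time course: a sham
group plus treated groups sampled at fixed hours after blood-brain-barrier
disruption, with a small number of replicates per group.  Differential
expression is a per-gene independent two-sample t-test (Welch by default)
on the normalized log2 scale, one comparison per (condition, timepoint)
against sham; a gene is a DEG if it passes both the effect-size and p-value
thresholds in at least one comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "TimecourseDEModel",
    "DEResults",
    "filter_unexpressed",
    "normalize",
    "quantile_normalize",
    "differential_expression",
    "call_degs",
    "deg_percentage",
    "enrich_gene_sets",
]

FC_MODES = {
    # effect threshold on the log2 scale
    "log2fc_gt2": 2.0,  # |log2 fold-change| > 2 (Results-text criterion)
    "fc_gt2": 1.0,      # fold-change > 2, i.e. |log2 fold-change| > 1
}


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM matrix with a per-sample design table.

    ``fpkm``: DataFrame indexed by gene_id with sample_id columns.
    ``design``: DataFrame indexed by sample_id with columns
    condition, timepoint_h, replicate.  Sham samples carry timepoint_h = 0.
    """

    fpkm: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.fpkm.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be nonnegative")
        missing = set(self.fpkm.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"design table missing samples: {sorted(missing)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.fpkm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.fpkm.columns

    def samples_in_group(self, condition: str, timepoint_h: float | None = None) -> list:
        d = self.design.loc[list(self.fpkm.columns)]
        m = d["condition"] == condition
        if timepoint_h is not None:
            m &= d["timepoint_h"] == timepoint_h
        return list(d.index[m])

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(fpkm=values, design=self.design)


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name -> set of gene ids)."""

    sets: dict

    def __post_init__(self) -> None:
        if len(set(self.sets)) != len(self.sets):
            raise ValueError("set names must be unique")
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = set(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def filter_unexpressed(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes whose FPKM is 0 in every sample; gene order preserved."""
    keep = (matrix.fpkm != 0).any(axis=1)
    return matrix.with_values(matrix.fpkm.loc[keep])


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one distribution.

    Each sample's values are replaced by the across-sample means of the
    order statistics at the same rank; ties receive the average of the rank
    means they span (average-rank convention).
    """
    arr = values.to_numpy(dtype=float)
    n = arr.shape[0]
    rank_means = np.sort(arr, axis=0).mean(axis=1)
    ranks = values.rank(axis=0, method="average").to_numpy()  # 1..n, ties averaged
    out = np.interp(ranks, np.arange(1, n + 1), rank_means)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(FPKM + 1) then quantile normalization across samples."""
    logged = np.log2(matrix.fpkm + 1.0)
    if logged.shape[1] < 2:
        warnings.warn("single-sample matrix: quantile step is the identity")
        return matrix.with_values(logged)
    return matrix.with_values(quantile_normalize(logged))


def differential_expression(
    norm: ExpressionMatrix,
    sham_samples: list,
    treat_samples: list,
    comparison: str = "",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene independent t-test of treatment vs sham on the log2 scale.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled variant).  Genes with zero variance in both groups get NaN
    t/p and are flagged; log2fc = mean(treatment) - mean(sham).

    Returns columns gene, comparison, log2fc, t_statistic, p_value, flag.
    """
    if len(sham_samples) < 2 or len(treat_samples) < 2:
        raise ValueError("need >= 2 replicates per group for a t-test")
    a = norm.fpkm[treat_samples].to_numpy(dtype=float)
    b = norm.fpkm[sham_samples].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant genes trigger scipy precision warnings; they are
        # flagged as degenerate below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, np.nan, p)
    return pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "comparison": comparison,
            "log2fc": log2fc,
            "t_statistic": t,
            "p_value": p,
            "flag": np.where(degenerate, "zero_variance", ""),
        }
    ).reset_index(drop=True)


def call_degs(
    table: pd.DataFrame, fc_mode: str = "log2fc_gt2", p_thresh: float = 0.05
) -> tuple[set, pd.DataFrame]:
    """Call DEGs across all comparisons and summarize per comparison.

    A gene is called if |log2fc| exceeds the mode's threshold AND
    p < p_thresh in at least one comparison.  Returns (called gene set,
    per-comparison summary with up/down counts).
    """
    if fc_mode not in FC_MODES:
        raise ValueError(f"unknown fc_mode {fc_mode!r}; choose from {sorted(FC_MODES)}")
    thresh = FC_MODES[fc_mode]
    t = table.copy()
    t["called"] = (
        (t["log2fc"].abs() > thresh) & (t["p_value"] < p_thresh)
    ).fillna(False)
    called = set(t.loc[t["called"], "gene"])
    rows = []
    for comp, grp in t.groupby("comparison", sort=False):
        hits = grp[grp["called"]]
        rows.append(
            {
                "comparison": comp,
                "n_up": int((hits["log2fc"] > 0).sum()),
                "n_down": int((hits["log2fc"] < 0).sum()),
                "n_called": int(len(hits)),
            }
        )
    return called, pd.DataFrame(rows)


def deg_percentage(n_called: int, n_total: int) -> float:
    """Percentage of transcripts called as DEGs, half-even-rounded to 2 dp."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_called > n_total:
        raise ValueError("n_called cannot exceed n_total")
    return float(np.round(100.0 * n_called / n_total, 2))


def enrich_gene_sets(
    called: set, universe: set, collection: GeneSetCollection
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    Set membership is intersected with the universe before testing;
    p-values are Benjamini-Hochberg adjusted across sets and the table is
    sorted by q.  Columns: set_name, overlap, set_size, universe_size,
    deg_count, p_value, q_value.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    called = set(called) & set(universe)
    M, N = len(universe), len(called)
    rows = []
    for name, genes in collection.items():
        in_universe = set(genes) & set(universe)
        n = len(in_universe)
        k = len(in_universe & called)
        # P(X >= k) for X ~ Hypergeom(M, n, N)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": n,
                "universe_size": M,
                "deg_count": N,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    # BH can only raise a p-value's threshold position, never shrink below p
    out["q_value"] = np.maximum(out["q_value"], out["p_value"])
    return out.sort_values("q_value", kind="stable").reset_index(drop=True)


class TimecourseDEModel:
    """Time-course differential-expression model for a sonication study.

    Built from a raw FPKM ExpressionMatrix; ``fit`` runs the full published
    pipeline: zero-expression filtering, log2(FPKM+1) quantile
    normalization, one t-test comparison per (condition, timepoint) against
    the sham group, and DEG calling under the fold-change + p rule.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        sham_condition: str = "sham",
        equal_var: bool = False,
    ):
        self.matrix = matrix
        self.sham_condition = sham_condition
        self.equal_var = equal_var

    def fit(
        self, fc_mode: str = "log2fc_gt2", p_thresh: float = 0.05
    ) -> "DEResults":
        filtered = filter_unexpressed(self.matrix)
        norm = normalize(filtered)
        sham = norm.samples_in_group(self.sham_condition)
        if not sham:
            raise ValueError(f"no samples in sham condition {self.sham_condition!r}")
        design = norm.design.loc[list(norm.sample_ids)]
        treated = design[design["condition"] != self.sham_condition]
        tables = []
        for (cond, tp), _ in treated.groupby(["condition", "timepoint_h"], sort=True):
            samples = norm.samples_in_group(cond, tp)
            tables.append(
                differential_expression(
                    norm,
                    sham,
                    samples,
                    comparison=f"{cond}@{tp:g}h",
                    equal_var=self.equal_var,
                )
            )
        table = pd.concat(tables, ignore_index=True)
        called, summary = call_degs(table, fc_mode=fc_mode, p_thresh=p_thresh)
        return DEResults(
            model=self,
            normalized=norm,
            table=table,
            called=called,
            comparison_summary=summary,
            fc_mode=fc_mode,
            p_thresh=p_thresh,
        )


@dataclass
class DEResults:
    model: TimecourseDEModel
    normalized: ExpressionMatrix
    table: pd.DataFrame
    called: set
    comparison_summary: pd.DataFrame
    fc_mode: str
    p_thresh: float

    @property
    def n_total(self) -> int:
        return int(self.normalized.fpkm.shape[0])

    @property
    def deg_percent(self) -> float:
        return deg_percentage(len(self.called), self.n_total)

    def log2fc_matrix(self, condition: str) -> pd.DataFrame:
        """Gene x timepoint log2FC matrix for one condition (heat-map input)."""
        sub = self.table[self.table["comparison"].str.startswith(f"{condition}@")]
        wide = sub.pivot(index="gene", columns="comparison", values="log2fc")
        tps = sorted(wide.columns, key=lambda c: float(c.split("@")[1][:-1]))
        wide = wide[tps]
        wide.columns = [float(c.split("@")[1][:-1]) for c in tps]
        return wide

    def enrich(self, collection: GeneSetCollection) -> pd.DataFrame:
        return enrich_gene_sets(
            self.called, set(self.normalized.gene_ids), collection
        )

    def summary(self) -> str:
        lines = [
            "Time-course differential expression",
            "===================================",
            f"transcripts analysed   {self.n_total:>8d}",
            f"DEGs called            {len(self.called):>8d}  ({self.deg_percent:.2f}%)",
            f"rule                   |log2FC| > {FC_MODES[self.fc_mode]:g} "
            f"and p < {self.p_thresh:g} in >= 1 comparison",
            "",
            self.comparison_summary.to_string(index=False),
        ]
        return "\n".join(lines)
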