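"""Glial-polarization marker-panel scoring.

Reactive microglia and astrocytes adopt distinct transcriptional states:
pro-inflammatory (M1 microglia, A1 astrocytes) versus
immunosuppressive/neuroprotective (M2, A2), alongside pan-reactive markers
shared by both.  This module scores named marker-gene panels on a
gene x timepoint log2 fold-change matrix (mean log2FC over the panel genes
present) and calls dominance of one subtype over another across a time
window when the score margin clears a threshold at every timepoint.

An ``unpolarized`` call is a first-class outcome — bulk tissue after
sonication frequently shows pan-microglial activation without a clean
M1/M2 split.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "MarkerPanel",
    "PanelScoreSeries",
    "load_default_panels",
    "load_panels",
    "panel_logfc_scores",
    "score_all_panels",
    "polarization_call",
]

_VALID_SUBTYPES = {
    "microglia": {"pan", "M1", "M2"},
    "astrocyte": {"pan", "A1", "A2"},
}

DEFAULT_MIN_MARGIN = 0.25  # log2 units


@dataclass
class MarkerPanel:
    """Named marker-gene list for one glial subtype."""

    name: str
    cell_type: str   # microglia | astrocyte
    subtype: str     # pan | M1 | M2 | A1 | A2
    genes: tuple

    def __post_init__(self) -> None:
        if self.cell_type not in _VALID_SUBTYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.subtype not in _VALID_SUBTYPES[self.cell_type]:
            raise ValueError(
                f"subtype {self.subtype!r} inconsistent with cell_type "
                f"{self.cell_type!r}"
            )
        if not self.genes:
            raise ValueError("panel gene list must be nonempty")
        self.genes = tuple(self.genes)


@dataclass
class PanelScoreSeries:
    """Per-timepoint mean log2FC of a panel plus gene coverage."""

    panel: str
    timepoints: np.ndarray   # h
    scores: np.ndarray       # mean log2FC over covered genes
    coverage: np.ndarray     # genes present per timepoint

    def score_at(self, t: float) -> float:
        idx = np.where(self.timepoints == t)[0]
        if idx.size == 0:
            raise KeyError(f"timepoint {t} not in series")
        return float(self.scores[idx[0]])


def load_panels(path) -> list[MarkerPanel]:
    """Read panels from a TSV with columns panel, cell_type, subtype, gene."""
    df = pd.read_csv(path, sep="\t")
    panels = []
    for (name, cell_type, subtype), grp in df.groupby(
        ["panel", "cell_type", "subtype"], sort=False
    ):
        panels.append(
            MarkerPanel(
                name=name,
                cell_type=cell_type,
                subtype=subtype,
                genes=tuple(grp["gene"]),
            )
        )
    return panels


def load_default_panels() -> list[MarkerPanel]:
    """Panels shipped with the package (the marker symbols printed in the
    source figures; substitute the full published panels for real data)."""
    ref = resources.files("fusbbbd.data").joinpath("glial_panels.tsv")
    with resources.as_file(ref) as path:
        return load_panels(path)


def panel_logfc_scores(
    log2fc: pd.DataFrame, panel: MarkerPanel
) -> PanelScoreSeries:
    """Score one panel on a gene x timepoint log2FC matrix.

    score(t) = mean log2FC over the panel genes present in the matrix at t;
    missing genes are excluded and reflected in the coverage count.
    """
    present = [g for g in panel.genes if g in log2fc.index]
    if not present:
        raise ValueError(f"no gene of panel {panel.name!r} present in the matrix")
    sub = log2fc.loc[present]
    scores = sub.mean(axis=0, skipna=True)
    coverage = sub.notna().sum(axis=0)
    return PanelScoreSeries(
        panel=panel.name,
        timepoints=np.asarray(log2fc.columns, dtype=float),
        scores=scores.to_numpy(dtype=float),
        coverage=coverage.to_numpy(dtype=int),
    )


def score_all_panels(
    log2fc: pd.DataFrame, panels: list[MarkerPanel]
) -> pd.DataFrame:
    """Long-format scores for several panels (panel, timepoint_h, score,
    coverage)."""
    rows = []
    for panel in panels:
        series = panel_logfc_scores(log2fc, panel)
        for t, s, c in zip(series.timepoints, series.scores, series.coverage):
            rows.append(
                {"panel": panel.name, "timepoint_h": t, "score": s, "coverage": c}
            )
    return pd.DataFrame(rows)


def polarization_call(
    score_a: PanelScoreSeries,
    score_b: PanelScoreSeries,
    window: list,
    min_margin: float = DEFAULT_MIN_MARGIN,
) -> str:
    """Call subtype dominance over a timepoint window.

    ``a_dominant`` iff score_a - score_b >= min_margin at every timepoint
    in the window; symmetric for ``b_dominant``; otherwise ``unpolarized``.
    """
    if len(window) == 0:
        raise ValueError("empty window")
    margins = np.array(
        [score_a.score_at(t) - score_b.score_at(t) for t in window]
    )
    if np.all(margins >= min_margin):
        return "a_dominant"
    if np.all(-margins >= min_margin):
        return "b_dominant"
    return "unpolarized"
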