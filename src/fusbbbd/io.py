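"""File interchange for every pipeline stage.

Formats: PCD recordings as HDF5 (datasets ``samples``, ``burst_onsets``;
attributes ``sampling_rate_hz``, ``fc_hz``, ``burst_length_s``) with a
two-column CSV fallback; DCE curves and variable-TR series as CSV;
expression matrices and design tables as TSV; gene sets as GMT; Cq tables
as CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cavitation import PCDRecording
from .dce import ConcentrationCurve, TRSeries
from .qpcr import CqTable
from .transcriptomics import ExpressionMatrix, GeneSetCollection

__all__ = [
    "write_pcd_hdf5",
    "read_pcd_hdf5",
    "write_pcd_csv",
    "read_pcd_csv",
    "write_curve_csv",
    "read_curve_csv",
    "write_tr_series_csv",
    "read_tr_series_csv",
    "write_expression_tsv",
    "read_expression_tsv",
    "read_gmt",
    "write_gmt",
    "write_cq_csv",
    "read_cq_csv",
]


# ---- PCD recordings ------------------------------------------------------


def write_pcd_hdf5(rec: PCDRecording, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples)
        f.create_dataset("burst_onsets", data=rec.burst_onsets)
        f.attrs["sampling_rate_hz"] = rec.sampling_rate
        f.attrs["fc_hz"] = rec.fundamental_fc
        f.attrs["burst_length_s"] = rec.burst_length


def read_pcd_hdf5(path) -> PCDRecording:
    import h5py

    with h5py.File(path, "r") as f:
        return PCDRecording(
            samples=f["samples"][...],
            burst_onsets=f["burst_onsets"][...],
            sampling_rate=float(f.attrs["sampling_rate_hz"]),
            fundamental_fc=float(f.attrs["fc_hz"]),
            burst_length=float(f.attrs["burst_length_s"]),
        )


def write_pcd_csv(rec: PCDRecording, path) -> None:
    """Two-column fallback (time_s, voltage); requires a flat 1-D trace."""
    if rec.samples.ndim != 1:
        raise ValueError("CSV fallback supports flat 1-D traces only")
    t = np.arange(rec.samples.size) / rec.sampling_rate
    pd.DataFrame({"time_s": t, "voltage": rec.samples}).to_csv(path, index=False)


def read_pcd_csv(
    path, burst_onsets, burst_length: float, fundamental_fc: float
) -> PCDRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise ValueError("CSV trace must be uniformly sampled")
    return PCDRecording(
        samples=df["voltage"].to_numpy(),
        sampling_rate=1.0 / dt[0],
        burst_onsets=np.asarray(burst_onsets, dtype=float),
        burst_length=burst_length,
        fundamental_fc=fundamental_fc,
    )


# ---- DCE curves ----------------------------------------------------------


def write_curve_csv(cp: ConcentrationCurve, ct: ConcentrationCurve, path) -> None:
    if not np.array_equal(cp.times, ct.times):
        raise ValueError("cp and ct must share a time grid for CSV export")
    pd.DataFrame(
        {"time_min": cp.times, "cp_mM": cp.values, "ct_mM": ct.values}
    ).to_csv(path, index=False)


def read_curve_csv(path) -> tuple[ConcentrationCurve, ConcentrationCurve]:
    df = pd.read_csv(path)
    t = df["time_min"].to_numpy()
    return (
        ConcentrationCurve(times=t, values=df["cp_mM"].to_numpy()),
        ConcentrationCurve(times=t, values=df["ct_mM"].to_numpy()),
    )


def write_tr_series_csv(series: TRSeries, path) -> None:
    pd.DataFrame({"tr_s": series.tr_values, "signal": series.signals}).to_csv(
        path, index=False
    )


def read_tr_series_csv(path) -> TRSeries:
    df = pd.read_csv(path)
    return TRSeries(
        tr_values=df["tr_s"].to_numpy(), signals=df["signal"].to_numpy()
    )


# ---- Expression ----------------------------------------------------------


def write_expression_tsv(matrix: ExpressionMatrix, matrix_path, design_path) -> None:
    matrix.fpkm.to_csv(matrix_path, sep="\t", index_label="gene")
    matrix.design.to_csv(design_path, sep="\t", index_label="sample_id")


def read_expression_tsv(matrix_path, design_path) -> ExpressionMatrix:
    fpkm = pd.read_csv(matrix_path, sep="\t", index_col="gene")
    design = pd.read_csv(design_path, sep="\t", index_col="sample_id")
    return ExpressionMatrix(fpkm=fpkm, design=design)


# ---- Gene sets -----------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """GMT: one set per line, tab-separated: name, description, genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


# ---- qPCR ----------------------------------------------------------------


def write_cq_csv(table: CqTable, cq_path, design_path) -> None:
    table.data.to_csv(cq_path, index=False)
    table.design.to_csv(design_path, index_label="sample_id")


def read_cq_csv(cq_path, design_path, reference_gene: str) -> CqTable:
    return CqTable(
        data=pd.read_csv(cq_path),
        design=pd.read_csv(design_path, index_col="sample_id"),
        reference_gene=reference_gene,
    )
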