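"""Readers and writers for the plain-text interchange formats.

Marker matrices travel as TSV (line_id, cycle[, family], then 0/1 marker
columns); phenotypes, plot records, QC reports and result tables as CSV;
kernels and Hat matrices as headered TSV (sparse Hat matrices additionally
in triplet form).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import KernelMatrix
from .markers import MarkerMatrix
from .predictors import HatMatrix
from .simdata import SimulatedPopulation

__all__ = [
    "read_marker_matrix", "write_marker_matrix",
    "read_phenotypes", "write_phenotypes",
    "read_kernel", "write_kernel",
    "write_hat_matrix", "write_hat_triplets",
]

_META_COLS = ("line_id", "cycle", "family")


def write_marker_matrix(markers: MarkerMatrix, path) -> None:
    df = pd.DataFrame(markers.X, columns=markers.marker_ids)
    df.insert(0, "line_id", markers.ids)
    df.insert(1, "cycle", markers.cycles)
    if markers.families is not None:
        df.insert(2, "family", markers.families)
    df.to_csv(path, sep="\t", index=False)


def read_marker_matrix(path) -> MarkerMatrix:
    """Read a marker TSV; rejects duplicates, missing calls and non-0/1 values."""
    df = pd.read_csv(path, sep="\t")
    if "line_id" not in df.columns or "cycle" not in df.columns:
        raise ValueError("marker file must start with line_id and cycle columns")
    meta = [c for c in _META_COLS if c in df.columns]
    marker_cols = [c for c in df.columns if c not in meta]
    if not marker_cols:
        raise ValueError("no marker columns found")
    block = df[marker_cols]
    if block.isna().any().any():
        col = block.columns[block.isna().any()][0]
        row = int(block[col].isna().idxmax())
        raise ValueError(f"missing marker call at row {row}, column {col!r}")
    values = block.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid marker value {values[i, j]!r} at row {i}, column {marker_cols[j]!r}"
        )
    return MarkerMatrix(
        X=values,
        ids=df["line_id"].to_numpy(),
        cycles=df["cycle"].to_numpy(),
        families=df["family"].to_numpy() if "family" in df.columns else None,
        marker_ids=np.array(marker_cols, dtype=object),
    )


def write_phenotypes(population: SimulatedPopulation, path) -> None:
    pd.DataFrame(
        {
            "line_id": population.ids,
            "cycle": population.cycles,
            "phenotype": population.phenotype,
            "true_bv": population.true_bv,
        }
    ).to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "line_id" not in df.columns or "phenotype" not in df.columns:
        raise ValueError("phenotype file needs line_id and phenotype columns")
    if df["line_id"].duplicated().any():
        raise ValueError("duplicate line IDs in phenotype file")
    return df


def write_kernel(K: KernelMatrix, path) -> None:
    df = pd.DataFrame(K.values, columns=K.ids)
    df.insert(0, "line_id", K.ids)
    df.to_csv(path, sep="\t", index=False)


def read_kernel(path, kind: str = "additive") -> KernelMatrix:
    df = pd.read_csv(path, sep="\t")
    ids = df["line_id"].to_numpy()
    return KernelMatrix(df.drop(columns="line_id").to_numpy(dtype=float), ids, kind)


def write_hat_matrix(hat: HatMatrix, path) -> None:
    df = pd.DataFrame(hat.B, columns=hat.training_ids)
    df.insert(0, "prediction_id", hat.prediction_ids)
    df.to_csv(path, sep="\t", index=False)


def write_hat_triplets(hat: HatMatrix, path) -> None:
    """Sparse triplet form: (prediction ID, training ID, coefficient), non-zeros only."""
    pi, ti = np.nonzero(hat.B)
    pd.DataFrame(
        {
            "prediction_id": hat.prediction_ids[pi],
            "training_id": hat.training_ids[ti],
            "coefficient": hat.B[pi, ti],
        }
    ).to_csv(path, sep="\t", index=False)


def ensure_outdir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out
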