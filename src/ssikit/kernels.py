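"""Genomic relationship and Gaussian kernels, kernel averaging, and partitioning.

The additive relationship matrix is built from column-standardised markers as
``G = Z Z' / p``.  Gaussian kernels use squared Euclidean distances on the raw
0/1 marker codes, scaled by the average squared distance over all ordered
pairs (diagonal included), so the scaled distances average exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markers import MarkerMatrix

__all__ = [
    "KernelMatrix",
    "center_scale_markers",
    "grm",
    "additive_kernel",
    "scaled_sq_distances",
    "gaussian_kernel",
    "gaussian_kernel_from_markers",
    "kernel_average",
    "partition_kernel",
]

#: bandwidths used for the three standard Gaussian kernels
DEFAULT_THETAS = (0.2, 1.0, 5.0)


@dataclass
class KernelMatrix:
    """Symmetric similarity matrix over a set of lines.

    ``kind`` is one of ``additive``, ``gaussian`` or ``averaged``; ``meta``
    stores provenance (theta, mean squared distance, averaging weights, ...).
    """

    values: np.ndarray
    ids: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kernel must be {n}x{n}, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("kernel matrix must be symmetric")
        if self.kind not in ("additive", "gaussian", "averaged"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, line_ids) -> np.ndarray:
        lookup = {lid: k for k, lid in enumerate(self.ids)}
        missing = [i for i in line_ids if i not in lookup]
        if missing:
            raise KeyError(f"IDs not in kernel: {missing[:5]}")
        return np.array([lookup[i] for i in line_ids], dtype=int)


def center_scale_markers(markers: MarkerMatrix | np.ndarray, ddof: int = 1) -> np.ndarray:
    """Column-standardise a marker matrix (mean 0, sd 1 per column).

    Raises on monomorphic columns — QC should have removed them.  ``ddof``
    selects the sd denominator convention (sample sd, ``ddof=1``, by default);
    it only rescales the resulting relationship matrix by a scalar.
    """
    X = markers.X if isinstance(markers, MarkerMatrix) else np.asarray(markers)
    X = X.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    mono = np.flatnonzero(sd == 0)
    if mono.size:
        names = (
            markers.marker_ids[mono[:5]].tolist()
            if isinstance(markers, MarkerMatrix)
            else mono[:5].tolist()
        )
        raise ValueError(f"monomorphic marker column(s), e.g. {names}; run QC first")
    return (X - mu) / sd


def grm(Z: np.ndarray, p: int, ids) -> KernelMatrix:
    """Additive genomic relationship matrix ``G = Z Z' / p``."""
    Z = np.asarray(Z, dtype=float)
    if p != Z.shape[1]:
        raise ValueError(f"p={p} does not match Z's column count {Z.shape[1]}")
    G = Z @ Z.T / p
    G = (G + G.T) / 2.0
    return KernelMatrix(G, ids, "additive", {"p": p})


def additive_kernel(markers: MarkerMatrix, ddof: int = 1) -> KernelMatrix:
    """Convenience: standardise markers and build the GRM in one step."""
    Z = center_scale_markers(markers, ddof=ddof)
    return grm(Z, markers.n_markers, markers.ids)


def scaled_sq_distances(
    markers: MarkerMatrix | np.ndarray, *, standardize: bool = False
) -> tuple[np.ndarray, float]:
    """Pairwise squared Euclidean distances scaled by their grand mean.

    Returns ``(d2_scaled, d_bar)`` where ``d_bar`` is the average of the raw
    squared distances over all n^2 ordered pairs (zero diagonal included) and
    ``mean(d2_scaled) == 1`` exactly.  Distances are computed on the raw 0/1
    codes unless ``standardize`` is set.
    """
    X = markers.X if isinstance(markers, MarkerMatrix) else np.asarray(markers)
    X = X.astype(float)
    if X.shape[0] < 2:
        raise ValueError("need at least two lines to compute pairwise distances")
    if standardize:
        X = center_scale_markers(X)
    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    np.maximum(d2, 0.0, out=d2)
    d_bar = d2.mean()
    if d_bar == 0:
        raise ValueError("all lines identical; distances are degenerate")
    d2 /= d_bar
    return d2, float(d_bar)


def gaussian_kernel(d2_scaled: np.ndarray, theta: float, ids) -> KernelMatrix:
    """Gaussian kernel ``K_ij = exp(-theta * d2_scaled_ij)``; unit diagonal."""
    if theta <= 0:
        raise ValueError(f"bandwidth theta must be > 0, got {theta}")
    K = np.exp(-theta * np.asarray(d2_scaled, dtype=float))
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, ids, "gaussian", {"theta": float(theta)})


def gaussian_kernel_from_markers(markers: MarkerMatrix, theta: float) -> KernelMatrix:
    d2, d_bar = scaled_sq_distances(markers)
    K = gaussian_kernel(d2, theta, markers.ids)
    K.meta["d_bar"] = d_bar
    return K


def kernel_average(kernels: list[KernelMatrix], variances) -> KernelMatrix:
    """Convex combination of kernels weighted by their genetic variances.

    ``w_k = sigma2_a_k / sum(sigma2_a)``; the members must share line order.
    """
    if len(kernels) < 2:
        raise ValueError("kernel averaging needs at least two kernels")
    variances = np.asarray(variances, dtype=float)
    if len(variances) != len(kernels):
        raise ValueError("one variance per kernel required")
    if (variances < 0).any():
        raise ValueError("variances must be non-negative")
    total = variances.sum()
    if total == 0:
        raise ValueError("at least one variance must be positive")
    ref = kernels[0].ids
    for K in kernels[1:]:
        if len(K.ids) != len(ref) or (K.ids != ref).any():
            raise ValueError("kernels must share the same line ordering")
    w = variances / total
    KA = np.zeros_like(kernels[0].values)
    for wk, K in zip(w, kernels):
        KA += wk * K.values
    return KernelMatrix(KA, ref, "averaged", {"weights": w.tolist()})


def partition_kernel(
    K: KernelMatrix, training_ids, prediction_ids
) -> tuple[np.ndarray, np.ndarray]:
    """Extract ``(K_TS, K_PS_TS)`` blocks in the order of the supplied ID lists."""
    training_ids = list(training_ids)
    prediction_ids = list(prediction_ids)
    if set(training_ids) & set(prediction_ids):
        raise ValueError("training and prediction IDs overlap")
    ti = K.index_of(training_ids)
    pi = K.index_of(prediction_ids)
    return K.values[np.ix_(ti, ti)], K.values[np.ix_(pi, ti)]
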