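"""BLUP Hat matrices, sparse selection indices, and penalty cross-validation.

The BLUP Hat matrix is ``B = K_PS,TS (K_TS + lambda0 I)^{-1}`` (computed by a
symmetric solve, never an explicit inverse).  The sparse index replaces each
row with the solution of the L1-penalized quadratic problem

    min_b 0.5 b'(K_TS + lambda0 I) b - g_i' b + lam ||b||_1,

solved row-by-row (rows are independent, parallelizable tasks) by cyclic
coordinate descent with soft-thresholding, warm starts along a descending
penalty grid, and an active-set speedup.  ``lam = 0`` recovers the BLUP row.
A single penalty for a run is chosen by k-fold cross-validation within the
training set, on a grid of fractions of the problem's ``lam_max`` so grid
points are comparable across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from ._cd import cd_path

__all__ = [
    "HatMatrix",
    "SSIPath",
    "CVResult",
    "PredictionResult",
    "blup_hat",
    "default_lambda_grid",
    "ssi_solve_path",
    "ssi_hat",
    "cross_validate_lambda",
    "predict",
    "kkt_violation",
    "ssi_objective",
]

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 1000


@dataclass
class HatMatrix:
    """Coefficients regressing predicted BVs on training phenotypes."""

    B: np.ndarray               # (n_PS, n_TS)
    prediction_ids: np.ndarray
    training_ids: np.ndarray
    lam: float                  # L1 penalty (0 for BLUP)
    lambda0: float
    kind: str = "blup"          # "blup" | "ssi"

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.prediction_ids = np.asarray(self.prediction_ids, dtype=object)
        self.training_ids = np.asarray(self.training_ids, dtype=object)
        if self.B.shape != (len(self.prediction_ids), len(self.training_ids)):
            raise ValueError("Hat matrix shape does not match the ID lists")

    @property
    def n_sup(self) -> np.ndarray:
        """Support size (non-zero coefficients) per prediction row."""
        return (self.B != 0).sum(axis=1)


@dataclass
class SSIPath:
    """Per-penalty solutions for one prediction individual."""

    lambdas: np.ndarray         # descending grid
    coefficients: np.ndarray    # (n_lambda, n_TS)
    support: np.ndarray         # per-lambda support size
    objective: np.ndarray       # per-lambda penalized objective value
    sweeps: np.ndarray


@dataclass
class CVResult:
    fractions: np.ndarray       # grid as fractions of lam_max
    fold_accuracy: np.ndarray   # (n_folds, n_fractions)
    mean_accuracy: np.ndarray
    selected_fraction: float
    lambda_cv: float            # selected fraction x the training problem's lam_max
    seed: int
    folds: list = field(repr=False, default_factory=list)


@dataclass
class PredictionResult:
    u_hat: np.ndarray
    prediction_ids: np.ndarray
    model: str
    n_sup: np.ndarray
    n_ts: int

    @property
    def mean_n_sup(self) -> float:
        return float(self.n_sup.mean())

    @property
    def pct_sparsity(self) -> float:
        """100 * mean(n_sup) / n_TS — share of the TS in the average support set."""
        return 100.0 * self.mean_n_sup / self.n_ts


def _check_system(K_ts: np.ndarray, lambda0: float) -> np.ndarray:
    K_ts = np.asarray(K_ts, dtype=float)
    if K_ts.ndim != 2 or K_ts.shape[0] != K_ts.shape[1]:
        raise ValueError("K_TS must be square")
    if not np.allclose(K_ts, K_ts.T, atol=1e-9):
        raise ValueError("K_TS must be symmetric")
    if lambda0 < 0:
        raise ValueError("lambda0 must be non-negative")
    return K_ts + lambda0 * np.eye(K_ts.shape[0])


def blup_hat(K_ts, K_ps_ts, lambda0, prediction_ids=None, training_ids=None) -> HatMatrix:
    """Dense BLUP Hat matrix via a symmetric positive-definite solve."""
    C = _check_system(K_ts, lambda0)
    K_ps_ts = np.atleast_2d(np.asarray(K_ps_ts, dtype=float))
    if K_ps_ts.shape[1] != C.shape[0]:
        raise ValueError("K_PS_TS column count must match K_TS")
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "training system is singular; use lambda0 > 0 with a PSD kernel"
        ) from exc
    B = cho_solve(cf, K_ps_ts.T).T
    n_ps, n_ts = B.shape
    if prediction_ids is None:
        prediction_ids = np.arange(n_ps)
    if training_ids is None:
        training_ids = np.arange(n_ts)
    return HatMatrix(B, prediction_ids, training_ids, lam=0.0, lambda0=lambda0, kind="blup")


def default_lambda_grid(lam_max: float, n_lambda: int = 100, min_fraction: float = 1e-3,
                        include_zero: bool = True) -> np.ndarray:
    """Geometric grid from lam_max down to min_fraction*lam_max (plus 0)."""
    if lam_max <= 0:
        return np.array([0.0])
    grid = np.geomspace(lam_max, min_fraction * lam_max, n_lambda)
    if include_zero:
        grid = np.append(grid, 0.0)
    return grid


def ssi_objective(C: np.ndarray, g: np.ndarray, b: np.ndarray, lam: float) -> float:
    """Penalized objective 0.5 b'Cb - g'b + lam*||b||_1."""
    return float(0.5 * b @ C @ b - g @ b + lam * np.abs(b).sum())


def kkt_violation(C: np.ndarray, g: np.ndarray, b: np.ndarray, lam: float) -> float:
    """Maximum stationarity violation of the L1 subgradient conditions."""
    grad = g - C @ b
    viol_zero = np.maximum(np.abs(grad[b == 0]) - lam, 0.0)
    nz = b != 0
    viol_nz = np.abs(grad[nz] - lam * np.sign(b[nz]))
    pieces = [v for v in (viol_zero, viol_nz) if v.size]
    return float(max(p.max() for p in pieces)) if pieces else 0.0


def ssi_solve_path(
    g_i: np.ndarray,
    C: np.ndarray,
    lam_grid: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SSIPath:
    """Coordinate-descent solutions for one prediction individual along a penalty path."""
    g = np.asarray(g_i, dtype=float).ravel()
    C = np.asarray(C, dtype=float)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if np.any(np.diff(lam_grid) > 0):
        raise ValueError("lambda grid must be non-increasing")
    lam_max = float(np.abs(g).max())
    if lam_grid[0] < lam_max - 1e-12:
        raise ValueError(f"lam_grid[0]={lam_grid[0]:.4g} is below lam_max={lam_max:.4g}")
    B, sweeps, ok = cd_path(C, g, lam_grid, tol, max_iter)
    if not ok.all():
        li = int(np.flatnonzero(~ok)[0])
        gap = kkt_violation(C, g, B[li], lam_grid[li])
        raise RuntimeError(
            f"coordinate descent did not converge at lambda index {li} "
            f"(lambda={lam_grid[li]:.4g}, KKT gap {gap:.3e})"
        )
    support = (B != 0).sum(axis=1)
    objective = np.array([ssi_objective(C, g, B[k], lam_grid[k]) for k in range(len(lam_grid))])
    return SSIPath(lam_grid, B, support, objective, sweeps)


def _row_solution(C, g, lam, tol, max_iter, warm_steps=10):
    """Solve one row at a single penalty, warm-starting from a short path."""
    lam_max = float(np.abs(g).max())
    if lam >= lam_max or lam_max == 0.0:
        return np.zeros(g.size)
    lo = max(lam, 1e-3 * lam_max)
    grid = np.geomspace(lam_max, lo, warm_steps)
    if lam < lo:
        grid = np.append(grid, lam)
    grid[-1] = lam
    B, _, ok = cd_path(C, g, grid, tol, max_iter)
    if not ok[-1]:
        raise RuntimeError(f"coordinate descent did not converge at lambda={lam:.4g}")
    return B[-1]


def ssi_hat(
    K_ts,
    K_ps_ts,
    lambda0,
    lam,
    prediction_ids=None,
    training_ids=None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> HatMatrix:
    """Row-sparse Hat matrix: one penalized solve per prediction individual.

    Rows are mutually independent; solving them in any order (or in parallel
    chunks) yields identical results.
    """
    C = _check_system(K_ts, lambda0)
    G = np.atleast_2d(np.asarray(K_ps_ts, dtype=float))
    if G.shape[1] != C.shape[0]:
        raise ValueError("K_PS_TS column count must match K_TS")
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    B = np.empty_like(G)
    for i in range(G.shape[0]):
        try:
            B[i] = _row_solution(C, G[i], lam, tol, max_iter)
        except RuntimeError as exc:
            raise RuntimeError(f"row {i}: {exc}") from None
    n_ps, n_ts = B.shape
    if prediction_ids is None:
        prediction_ids = np.arange(n_ps)
    if training_ids is None:
        training_ids = np.arange(n_ts)
    return HatMatrix(B, prediction_ids, training_ids, lam=lam, lambda0=lambda0, kind="ssi")


def _fold_split(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, n_folds)]


def cross_validate_lambda(
    y_ts: np.ndarray,
    K_ts,
    lambda0: float,
    n_folds: int = 10,
    fractions: np.ndarray | None = None,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CVResult:
    """Select the L1 penalty by k-fold CV within the training set.

    Each fold is treated as a pseudo-prediction set; penalty grids are
    fractions of each fold problem's lam_max so grid indices align across
    folds.  The returned ``lambda_cv`` is the winning fraction times the full
    training problem's lam_max (largest off-diagonal training similarity).
    Ties in mean accuracy break toward the larger (sparser) fraction.
    The default solver tolerance is looser than the path default: CV only
    ranks penalties, so coefficient-level precision is not needed.
    """
    y = np.asarray(y_ts, dtype=float)
    K = np.asarray(K_ts.values if hasattr(K_ts, "values") else K_ts, dtype=float)
    n = y.size
    if n < n_folds:
        raise ValueError("training set smaller than the number of folds")
    if n // n_folds < 3:
        raise ValueError("folds would have < 3 individuals; use fewer folds")
    if fractions is None:
        fractions = np.append(np.geomspace(1.0, 1e-2, 12), 0.0)
    fractions = np.asarray(fractions, dtype=float)
    if np.any(np.diff(fractions) > 0):
        raise ValueError("fractions must be non-increasing")

    rng = np.random.default_rng(seed)
    folds = _fold_split(n, n_folds, rng)
    acc = np.full((n_folds, fractions.size), np.nan)
    pos = fractions > 0
    for f, val_idx in enumerate(folds):
        tr_idx = np.setdiff1d(np.arange(n), val_idx)
        C = K[np.ix_(tr_idx, tr_idx)] + lambda0 * np.eye(tr_idx.size)
        Gv = K[np.ix_(val_idx, tr_idx)]
        y_tr = y[tr_idx] - y[tr_idx].mean()
        y_val = y[val_idx]
        lam_max = float(np.abs(Gv).max())
        lams = fractions[pos] * lam_max
        preds = np.zeros((fractions.size, val_idx.size))
        for i in range(val_idx.size):
            B, _, ok = cd_path(C, Gv[i], lams, tol, max_iter)
            if not ok.all():
                raise RuntimeError(f"CV fold {f}, row {i}: coordinate descent did not converge")
            preds[pos, i] = B @ y_tr
        if (~pos).any():
            # the unpenalized endpoint is the BLUP row: solve it exactly
            cf = cho_factor(C, lower=True)
            B0 = cho_solve(cf, Gv.T).T
            preds[~pos] = B0 @ y_tr
        for li in range(fractions.size):
            p = preds[li]
            if p.std() > 0 and y_val.std() > 0:
                acc[f, li] = float(np.corrcoef(y_val, p)[0, 1])
    mean_acc = np.nanmean(
        np.where(np.isnan(acc), -np.inf, acc), axis=0
    )
    best = int(np.flatnonzero(mean_acc == mean_acc.max())[0])  # grid descends: first = sparsest
    off = K - np.diag(np.diag(K))
    lam_max_full = float(np.abs(off).max())
    return CVResult(
        fractions=fractions,
        fold_accuracy=acc,
        mean_accuracy=mean_acc,
        selected_fraction=float(fractions[best]),
        lambda_cv=float(fractions[best] * lam_max_full),
        seed=seed,
        folds=folds,
    )


def predict(hat: HatMatrix, y_ts_centered: np.ndarray, model: str = "") -> PredictionResult:
    """Predicted breeding values u_hat = B y_TS plus sparsity summaries."""
    y = np.asarray(y_ts_centered, dtype=float)
    if y.size != hat.B.shape[1]:
        raise ValueError("phenotype vector length does not match the Hat matrix")
    return PredictionResult(
        u_hat=hat.B @ y,
        prediction_ids=hat.prediction_ids,
        model=model or hat.kind,
        n_sup=hat.n_sup,
        n_ts=hat.B.shape[1],
    )
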