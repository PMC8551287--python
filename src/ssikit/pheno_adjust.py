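"""Adjusted phenotypes (BLUEs) from plot-level trial records.

Two mixed models are supported, both with a single random effect (the
incomplete block within replicate), which allows REML to be profiled down to
a one-dimensional search over the variance ratio gamma = sigma2_b / sigma2_e:

* multi-location:  Y = mu + G + L + R(L) + B(R,L) + GxL + e
* single-location: Y = mu + G + R + B(R) + e

Genotype, location, replicate and interaction effects are fixed; blocks are
iid random.  The per-genotype adjusted value is ``mu_hat + G_hat_i`` under
sum-to-zero constraints on the non-genotype fixed effects, i.e. the genotype
BLUE freed of design effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = ["AdjustedPhenotypes", "fit_multilocation_model", "fit_singlelocation_model",
           "center_phenotypes"]

REQUIRED_COLS = ("genotype", "rep", "block", "value")


@dataclass
class AdjustedPhenotypes:
    """Per-genotype BLUEs plus the adjustment model's variance estimates."""

    values: pd.Series          # genotype -> adjusted value
    std_errors: pd.Series      # genotype -> standard error
    sigma2_block: float
    sigma2_error: float
    model: str                 # "multilocation" | "singlelocation"

    def reindex(self, ids) -> np.ndarray:
        return self.values.reindex(ids).to_numpy()


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list]:
    cats = sorted(labels.unique())
    M = (labels.to_numpy()[:, None] == np.array(cats)[None, :]).astype(float)
    return M, cats


def _sum_contrast(labels: pd.Series) -> np.ndarray:
    """Sum-to-zero contrast columns: [x == level_k] - [x == last_level], k < last."""
    M, cats = _indicator(labels)
    if len(cats) < 2:
        return np.empty((len(labels), 0))
    return M[:, :-1] - M[:, -1:]


def _block_groups(labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    codes, _ = pd.factorize(labels)
    sizes = np.bincount(codes)
    return codes, sizes


def _whiten(A: np.ndarray, codes: np.ndarray, sizes: np.ndarray, gamma: float) -> np.ndarray:
    """Apply (I + gamma Z Z')^{-1/2} where Z is the block indicator.

    Blocks are disjoint groups, so V is block-diagonal with I + gamma*J per
    group; the inverse square root shrinks each group's mean component.
    """
    if gamma == 0.0:
        return A
    out = A.astype(float).copy()
    one_d = out.ndim == 1
    if one_d:
        out = out[:, None]
    for g in range(sizes.size):
        idx = np.flatnonzero(codes == g)
        m = sizes[g]
        c = (1.0 / np.sqrt(1.0 + gamma * m) - 1.0) / m
        out[idx] += c * out[idx].sum(axis=0, keepdims=True)
    return out[:, 0] if one_d else out


def _reml_gamma(y: np.ndarray, Xr: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    """Profiled REML over gamma = sigma2_b/sigma2_e for V = sigma2_e (I + gamma ZZ')."""
    n, r = Xr.shape

    def neg2_reml(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        yt = _whiten(y, codes, sizes, gamma)
        Xt = _whiten(Xr, codes, sizes, gamma)
        beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        rss = float(((yt - Xt @ beta) ** 2).sum())
        logdet_v = float(np.log1p(gamma * sizes).sum())
        sign, logdet_xx = np.linalg.slogdet(Xt.T @ Xt)
        if sign <= 0:
            return np.inf
        return (n - r) * np.log(rss) + logdet_v + logdet_xx

    res = minimize_scalar(neg2_reml, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-8})
    gamma_hat = float(np.exp(res.x))
    # compare against the gamma -> 0 boundary (pure fixed-effects model)
    if neg2_reml(-30.0) <= res.fun:
        return 0.0
    return gamma_hat


def _fit(records: pd.DataFrame, multilocation: bool) -> AdjustedPhenotypes:
    df = records.copy()
    needed = REQUIRED_COLS + (("location",) if multilocation else ())
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    if df["value"].isna().any():
        raise ValueError("records contain missing trait values")

    geno = df["genotype"].astype(str)
    G, geno_levels = _indicator(geno)
    parts = [G]
    if multilocation:
        loc = df["location"].astype(str)
        if loc.nunique() < 2:
            raise ValueError("multi-location model requires >= 2 locations")
        # genotypes observed in a single location are fine; a location with a
        # single genotype aliases G with L
        for l, sub in df.groupby(loc.rename("loc")):
            if sub["genotype"].nunique() == 1 and len(geno_levels) > 1:
                raise ValueError(
                    f"genotype aliased with location {l!r}: only one genotype observed there"
                )
        L = _sum_contrast(loc)
        parts.append(L)
        # replicate within location
        for lv in sorted(loc.unique()):
            parts.append(_rep_within(df, loc, lv))
        # GxL interaction contrasts
        Gc = _sum_contrast(geno)
        if L.shape[1] and Gc.shape[1]:
            inter = np.einsum("ni,nj->nij", Gc, L).reshape(len(df), -1)
            parts.append(inter)
        block_labels = loc + "|" + df["rep"].astype(str) + "|" + df["block"].astype(str)
    else:
        if "location" in df.columns and df["location"].nunique() > 1:
            raise ValueError("single-location model got records from multiple locations")
        parts.append(_sum_contrast(df["rep"].astype(str)))
        block_labels = df["rep"].astype(str) + "|" + df["block"].astype(str)

    X = np.concatenate(parts, axis=1)
    y = df["value"].to_numpy(dtype=float)
    codes, sizes = _block_groups(block_labels)

    # full-column-rank subset (pivoted QR) for the REML profile
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag[0] * 1e-10).sum()) if diag.size else 0
    if rank < X.shape[1]:
        logger.warning(
            "design rank %d < %d columns; inestimable contrasts (e.g. GxL cells) "
            "resolved by the minimum-norm solution", rank, X.shape[1]
        )
    Xr = X[:, piv[:rank]]

    gamma = _reml_gamma(y, Xr, codes, sizes)
    yt = _whiten(y, codes, sizes, gamma)
    Xt = _whiten(X, codes, sizes, gamma)
    beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    dof = max(len(y) - rank, 1)
    sigma2_e = float(resid @ resid) / dof
    sigma2_b = gamma * sigma2_e

    n_g = len(geno_levels)
    adjusted = pd.Series(beta[:n_g], index=geno_levels, name="adjusted")
    XtX_pinv = np.linalg.pinv(Xt.T @ Xt)
    se = pd.Series(np.sqrt(np.maximum(sigma2_e * np.diag(XtX_pinv)[:n_g], 0.0)),
                   index=geno_levels, name="se")
    return AdjustedPhenotypes(
        values=adjusted,
        std_errors=se,
        sigma2_block=sigma2_b,
        sigma2_error=sigma2_e,
        model="multilocation" if multilocation else "singlelocation",
    )


def _rep_within(df: pd.DataFrame, loc: pd.Series, level: str) -> np.ndarray:
    """Sum-to-zero replicate contrasts restricted to one location (zero elsewhere)."""
    mask = (loc == level).to_numpy()
    reps = df["rep"].astype(str)
    cats = sorted(reps[mask].unique())
    if len(cats) < 2:
        return np.empty((len(df), 0))
    M = (reps.to_numpy()[:, None] == np.array(cats)[None, :]).astype(float)
    C = (M[:, :-1] - M[:, -1:]) * mask[:, None]
    return C


def fit_multilocation_model(records: pd.DataFrame) -> AdjustedPhenotypes:
    """Fit Y = mu + G + L + R(L) + B(L,R) + GxL + e and return genotype BLUEs."""
    return _fit(records, multilocation=True)


def fit_singlelocation_model(records: pd.DataFrame) -> AdjustedPhenotypes:
    """Fit Y = mu + G + R + B(R) + e and return genotype BLUEs."""
    return _fit(records, multilocation=False)


def center_phenotypes(adjusted, ids, reference_ids) -> np.ndarray:
    """Centre a phenotype vector by the mean over the reference (training) IDs."""
    values = np.asarray(adjusted, dtype=float)
    ids = list(ids)
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValueError("reference ID set is empty")
    lookup = {lid: k for k, lid in enumerate(ids)}
    ref_idx = [lookup[i] for i in reference_ids]
    return values - values[ref_idx].mean()
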