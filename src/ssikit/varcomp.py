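"""Variance-component estimation on the training set.

``reml_single_kernel`` maximizes the likelihood of y ~ N(0, s2_u K + s2_e I)
by eigendecomposition of K and a one-dimensional search over the variance
ratio (phenotypes are centred, the model carries no fixed effects, so the
restricted and full likelihoods coincide).  ``gibbs_multi_kernel`` samples
the three-kernel random-effects model y = u1 + u2 + u3 + e with
scaled-inverse-chi-square priors and returns posterior means, providing the
kernel-specific variances used for kernel averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from .kernels import KernelMatrix

__all__ = ["VarianceComponents", "reml_single_kernel", "gibbs_multi_kernel", "variance_ratio"]

_EIG_TOL = 1e-8


@dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float
    estimator: str                      # "reml" | "gibbs"
    kernel_variances: np.ndarray | None = None  # per-kernel genetic variances

    def __post_init__(self) -> None:
        if self.sigma2_u < 0 or self.sigma2_e < 0:
            raise ValueError("variances must be non-negative")
        if self.kernel_variances is not None:
            self.kernel_variances = np.asarray(self.kernel_variances, dtype=float)
            if not np.isclose(self.kernel_variances.sum(), self.sigma2_u, rtol=1e-6, atol=1e-12):
                raise ValueError("kernel variances must sum to sigma2_u")

    @property
    def lambda0(self) -> float:
        return variance_ratio(self)

    @property
    def h2(self) -> float:
        total = self.sigma2_u + self.sigma2_e
        return self.sigma2_u / total if total > 0 else 0.0


def variance_ratio(vc: VarianceComponents) -> float:
    """lambda0 = sigma2_e / sigma2_u (the BLUP ridge term)."""
    if vc.sigma2_u <= 0:
        raise ValueError("sigma2_u must be positive for the BLUP ratio")
    return vc.sigma2_e / vc.sigma2_u


def _kernel_values(K) -> np.ndarray:
    return K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def reml_single_kernel(
    y_ts: np.ndarray, K_ts, *, min_n: int = 10, h2_bounds: tuple[float, float] = (1e-4, 1 - 1e-4)
) -> VarianceComponents:
    """Deterministic variance estimates for the single-kernel model.

    Works in the kernel's eigenbasis where the covariance is diagonal:
    var(y_tilde_i) = s2_u * (d_i + lambda0).  The profile over s2_u is
    closed-form, leaving a bounded scalar optimization over h2.
    """
    y = np.asarray(y_ts, dtype=float)
    K = _kernel_values(K_ts)
    n = y.size
    if n < min_n:
        raise ValueError(f"need at least {min_n} training lines, got {n}")
    if K.shape != (n, n):
        raise ValueError("kernel shape does not match phenotype length")
    d, U = eigh(K)
    if d.min() < -_EIG_TOL * max(1.0, d.max()):
        raise ValueError(f"kernel is not PSD (min eigenvalue {d.min():.3e})")
    d = np.maximum(d, 0.0)
    yt2 = (U.T @ y) ** 2

    def neg2ll(h2: float) -> float:
        lam0 = (1.0 - h2) / h2
        dv = d + lam0
        s2u = float(np.mean(yt2 / dv))
        if s2u <= 0:
            return np.inf
        return n * np.log(s2u) + float(np.log(dv).sum())

    res = minimize_scalar(neg2ll, bounds=h2_bounds, method="bounded",
                          options={"xatol": 1e-10})
    h2_hat = float(res.x)
    if h2_hat <= h2_bounds[0] * 2 or h2_hat >= 1 - 2 * (1 - h2_bounds[1]):
        warnings.warn(f"REML solution at the boundary (h2={h2_hat:.4g})")
    lam0 = (1.0 - h2_hat) / h2_hat
    s2u = float(np.mean(yt2 / (d + lam0)))
    return VarianceComponents(sigma2_u=s2u, sigma2_e=lam0 * s2u, estimator="reml")


def gibbs_multi_kernel(
    y_ts: np.ndarray,
    kernels: list,
    n_iter: int = 12000,
    burn_in: int = 2000,
    seed: int = 0,
    df0: float = 5.0,
) -> VarianceComponents:
    """Gibbs sampler for y = sum_k u_k + e with u_k ~ N(0, s2_ak K_k).

    Each genetic term is sampled in its kernel's eigenbasis (diagonal
    conditional posteriors).  Priors are scaled-inverse-chi-square with
    ``df0`` degrees of freedom; prior scales are set so each term's prior
    mode explains an equal share of half the sample variance of y.
    """
    y = np.asarray(y_ts, dtype=float)
    n = y.size
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    nk = len(kernels)
    vary = float(y.var())
    if vary == 0:
        warnings.warn("zero-variance phenotypes; posterior collapses to the prior scale")
        vary = 1.0
    rng = np.random.default_rng(seed)

    gammas, lams = [], []
    for K in kernels:
        d, U = eigh(_kernel_values(K))
        keep = d > _EIG_TOL * max(1.0, d.max())
        gammas.append(U[:, keep])
        lams.append(d[keep])

    # prior modes: genetic terms share half the phenotypic variance equally
    mode_g = 0.5 * vary / nk
    mode_e = 0.5 * vary
    S0_g = mode_g * (df0 + 2.0) / df0
    S0_e = mode_e * (df0 + 2.0) / df0

    s2a = np.full(nk, mode_g)
    s2e = mode_e
    u = np.zeros((nk, n))
    sum_s2a = np.zeros(nk)
    sum_s2e = 0.0

    for it in range(n_iter):
        for k in range(nk):
            resid_k = y - u.sum(axis=0) + u[k]
            G, lam = gammas[k], lams[k]
            yt = G.T @ resid_k
            post_var = 1.0 / (1.0 / s2e + 1.0 / (s2a[k] * lam))
            post_mean = post_var * yt / s2e
            delta = post_mean + np.sqrt(post_var) * rng.standard_normal(lam.size)
            u[k] = G @ delta
            ss = float((delta ** 2 / lam).sum())
            dfp = df0 + lam.size
            s2a[k] = (ss + df0 * S0_g) / rng.chisquare(dfp)
        e = y - u.sum(axis=0)
        s2e = float((e @ e + df0 * S0_e) / rng.chisquare(df0 + n))
        if not (np.isfinite(s2e) and np.isfinite(s2a).all()):
            raise RuntimeError(f"Gibbs chain diverged at iteration {it}")
        if it >= burn_in:
            sum_s2a += s2a
            sum_s2e += s2e

    kept = n_iter - burn_in
    post_a = sum_s2a / kept
    return VarianceComponents(
        sigma2_u=float(post_a.sum()),
        sigma2_e=sum_s2e / kept,
        estimator="gibbs",
        kernel_variances=post_a,
    )
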