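"""Marker quality control: segregation-distortion test with BH FDR, then MAF filter.

Dominant 0/1 markers from DH families are expected to segregate 3:1
(presence:absence) when both the band-present and band-absent alleles
segregate; markers deviating from the expected ratio at a 5% false
discovery rate are discarded, and the survivors are filtered at
MAF >= 0.05, where MAF = min(presence frequency, 1 - presence frequency).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .markers import MarkerMatrix

__all__ = ["segregation_test", "bh_adjust", "qc_pipeline"]


def segregation_test(
    marker_column: np.ndarray,
    expected_ratio: tuple[float, float] = (3.0, 1.0),
    method: str = "chi2",
) -> tuple[float, float]:
    """Goodness-of-fit test of presence/absence counts against an expected ratio.

    ``method='chi2'`` is the 1-df chi-square test; ``method='binom'`` runs an
    exact two-sided binomial test instead.  Returns ``(statistic, p_value)``
    (for the binomial test the statistic is the presence count).
    """
    x = np.asarray(marker_column)
    if x.size == 0:
        raise ValueError("empty marker column")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("marker column must contain only 0/1 calls")
    a, b = expected_ratio
    if a <= 0 or b <= 0:
        raise ValueError("expected ratio components must be positive")
    n = x.size
    n_present = int(x.sum())
    p_present = a / (a + b)
    if method == "binom":
        res = stats.binomtest(n_present, n, p_present)
        return float(n_present), float(res.pvalue)
    if method != "chi2":
        raise ValueError(f"unknown method {method!r}")
    observed = np.array([n_present, n - n_present], dtype=float)
    expected = np.array([n * p_present, n * (1 - p_present)])
    stat = float(((observed - expected) ** 2 / expected).sum())
    pval = float(stats.chi2.sf(stat, df=1))
    return stat, pval


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def qc_pipeline(
    markers: MarkerMatrix,
    alpha_fdr: float = 0.05,
    maf_min: float = 0.05,
    expected_ratio: tuple[float, float] = (3.0, 1.0),
    method: str = "chi2",
) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Run the two-stage QC chain and return (filtered matrix, full report).

    Stage 1 removes markers whose segregation deviates from ``expected_ratio``
    at the BH-adjusted ``alpha_fdr``; stage 2 removes survivors with
    MAF < ``maf_min``.  The report covers every input marker with both
    criteria recorded regardless of removal order.
    """
    if markers.n_markers == 0:
        raise ValueError("marker matrix has no markers")
    n = markers.n_lines
    counts = markers.X.sum(axis=0).astype(int)
    stats_p = [
        segregation_test(markers.X[:, j], expected_ratio, method=method)
        for j in range(markers.n_markers)
    ]
    stat = np.array([s for s, _ in stats_p])
    pval = np.array([p for _, p in stats_p])
    padj = bh_adjust(pval)
    freq = counts / n
    maf = np.minimum(freq, 1 - freq)

    distorted = padj < alpha_fdr
    low_maf = maf < maf_min
    retained = ~distorted & ~low_maf
    reason = np.where(distorted, "distortion", np.where(low_maf, "maf", "none"))

    report = pd.DataFrame(
        {
            "marker_id": markers.marker_ids,
            "n_present": counts,
            "statistic": stat,
            "p_value": pval,
            "p_adj": padj,
            "maf": maf,
            "retained": retained,
            "reason": reason,
        }
    )
    if not retained.any():
        warnings.warn("QC removed every marker; returning an empty matrix")
    return markers.select_markers(retained), report
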