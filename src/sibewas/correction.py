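"""Multiple-testing control and genomic-inflation diagnostics.

Bonferroni thresholds, Benjamini-Hochberg step-up q-values, the genomic
inflation factor lambda (median association chi-square over the null 1-df
median 0.4549), QQ-plot coordinates, and principal components of the
methylome used to absorb unmeasured global confounders.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class InflationSummary:
    lambda_: float
    n_tests: int
    qq_points: pd.DataFrame  # columns: expected, observed (-log10 p)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Nominal per-test threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be at least 1, got {m}")
    return alpha / m


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q(i) = min_{j >= i} p(j) * m / j over the sorted p-values, mapped back
    to the input order; output lies in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def genomic_inflation(pvals) -> InflationSummary:
    """Inflation factor and QQ coordinates for a vector of p-values.

    Each p is converted to a 1-df chi-square quantile; lambda is the ratio
    of the median of those statistics to the null median.  QQ points pair
    the uniform order statistics i/(m+1) with the sorted observed p-values,
    both on the -log10 scale.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size < 100:
        raise ValueError(f"need at least 100 p-values for a stable median, got {p.size}")
    if (p == 0).any():
        warnings.warn("p-values of 0 clipped to the smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, None)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    lam = float(np.median(chi2) / CHI2_1DF_MEDIAN)
    m = p.size
    expected = -np.log10(np.arange(1, m + 1) / (m + 1))
    observed = -np.log10(np.sort(p))
    qq = pd.DataFrame({"expected": expected, "observed": observed})
    return InflationSummary(lambda_=lam, n_tests=m, qq_points=qq)


def methylome_pca(beta, k: int = 3) -> pd.DataFrame:
    """Top-k principal components of the probe-standardized beta matrix.

    Rows of the result are samples; the scores are appended to the EWAS
    covariates to absorb global confounders (batch, cell-type drift).
    """
    bdf = beta.values if hasattr(beta, "offset_alpha") else beta
    if k < 1:
        raise ValueError(f"k must be at least 1, got {k}")
    vals = bdf.to_numpy(dtype=float)  # probes x samples
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    keep = (sd > 0).ravel()
    z = (vals[keep] - mean[keep]) / sd[keep]
    u_mat, s, _ = np.linalg.svd(z.T, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank {rank} of the beta matrix")
    scores = u_mat[:, :k] * s[:k]
    return pd.DataFrame(
        scores, index=bdf.columns, columns=[f"mPC{i+1}" for i in range(k)]
    )
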