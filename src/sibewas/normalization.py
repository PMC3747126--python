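"""Control-probe normalization and beta-value computation.

Chip and batch effects reach target and control probes alike, so principal
components of the standardized control-probe matrix estimate the shared
technical variation.  Each probe's log-intensities (both channels
independently) are regressed on those orthogonal control scores across
samples; residuals plus the fitted intercept, exponentiated back, give
normalized intensities on the original scale.  Beta-values then follow the
platform convention M / (M + U + alpha) with offset alpha = 100.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, ControlPCA, IntensityPair


def orthogonalize_controls(controls: pd.DataFrame, k: int | None = None) -> ControlPCA:
    """Principal components of the standardized control-probe matrix.

    Each control feature is centred and scaled to unit variance across
    samples before the decomposition; zero-variance features are left
    centred only.  When ``k`` is None the number of components follows the
    Kaiser rule (eigenvalue above 1 on the standardized features).
    """
    vals = controls.to_numpy(dtype=float)
    n_feat, n_samples = vals.shape
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    nonconst = (sd > 0).ravel()
    if not nonconst.any():
        raise ValueError("all control features are constant across samples")
    z = np.zeros_like(vals)
    z[nonconst] = (vals[nonconst] - mean[nonconst]) / sd[nonconst]

    # SVD of samples x features matrix
    u_mat, s, vt = np.linalg.svd(z.T, full_matrices=False)
    eigvals = s**2 / (n_samples - 1)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if k is None:
        k = max(1, int((eigvals > 1.0).sum()))
    if k < 1:
        raise ValueError(f"k must be at least 1, got {k}")
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank {rank} of the control matrix")
    scores = u_mat[:, :k] * s[:k]
    return ControlPCA(
        component_scores=pd.DataFrame(
            scores, index=controls.columns, columns=[f"cPC{i+1}" for i in range(k)]
        ),
        loadings=pd.DataFrame(
            vt[:k].T, index=controls.index, columns=[f"cPC{i+1}" for i in range(k)]
        ),
        explained_variance=eigvals[:k],
        k=k,
    )


def regress_out_controls(intensities: IntensityPair, pca: ControlPCA) -> IntensityPair:
    """Remove control-predicted variation from both intensity channels.

    Per probe and channel, log(intensity + 1) is regressed across samples on
    the control scores; the output is exp(intercept + residual) - 1, floored
    at zero, so normalized intensities stay on the original scale and the
    residual correlation with every control score is ~0.
    """
    scores = pca.component_scores
    if not intensities.sample_ids.equals(scores.index):
        scores = scores.loc[intensities.sample_ids]
    n = scores.shape[0]
    if n <= pca.k + 1:
        raise ValueError(
            f"need more samples ({n}) than control predictors + 1 ({pca.k + 1})"
        )
    design = np.column_stack([np.ones(n), scores.to_numpy()])
    # hat projection computed once; applied to all probes of both channels
    pinv = np.linalg.pinv(design)

    def _clean(df: pd.DataFrame) -> pd.DataFrame:
        logi = np.log(df.to_numpy(dtype=float) + 1.0)  # probes x samples
        coefs = pinv @ logi.T  # (k+1) x probes
        fitted = design @ coefs  # samples x probes
        resid = logi - fitted.T
        out = np.exp(coefs[0][:, None] + resid) - 1.0
        return pd.DataFrame(
            np.maximum(out, 0.0), index=df.index, columns=df.columns
        )

    return IntensityPair(
        _clean(intensities.methylated), _clean(intensities.unmethylated)
    )


def compute_beta(intensities: IntensityPair, alpha: float = 100.0) -> BetaMatrix:
    """Beta-values M / (M + U + alpha), entrywise in [0, 1)."""
    if alpha < 0:
        raise ValueError(f"offset alpha must be non-negative, got {alpha}")
    m = intensities.methylated.to_numpy(dtype=float)
    u = intensities.unmethylated.to_numpy(dtype=float)
    denom = m + u + alpha
    with np.errstate(invalid="ignore"):
        b = np.where(denom > 0, m / denom, 0.0)
    return BetaMatrix(
        values=pd.DataFrame(
            b, index=intensities.probe_ids, columns=intensities.sample_ids
        ),
        offset_alpha=alpha,
    )


def normalize_pipeline(
    intensities: IntensityPair,
    controls: pd.DataFrame,
    k: int | None = None,
    alpha: float = 100.0,
) -> tuple[BetaMatrix, ControlPCA]:
    """Orthogonalize controls, regress them out, and compute beta-values."""
    pca = orthogonalize_controls(controls, k=k)
    cleaned = regress_out_controls(intensities, pca)
    return compute_beta(cleaned, alpha=alpha), pca
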