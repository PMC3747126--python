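"""Per-site association of ln CRP with methylation under sibship relatedness.

Each site is fitted with a linear mixed model

    lnCRP_ij = beta0 + beta_x * meth_ij + gamma' covariates_ij + b_i + e_ij

where b_i ~ N(0, sigma_sib^2) is a sibship random intercept and
e_ij ~ N(0, sigma_res^2).  Estimation is restricted maximum likelihood,
profiled down to the single variance ratio theta = sigma_sib^2/sigma_res^2:
for a random-intercept model the covariance inverse has the closed
Woodbury form per sibship, so each likelihood evaluation costs O(n) and a
whole epigenome scan runs in seconds.  Inference on the exposure is a
two-sided Wald z-test.  Cohorts of unrelated individuals (all sibships
singletons), or fits where the sibship variance collapses to zero, reduce
to ordinary least squares, which is then reported (with t-based p-values)
and flagged via the variance components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "bmi", "current_smoker")


class DegenerateExposureError(ValueError):
    """The exposure is constant, so its coefficient is not estimable."""


@dataclass
class ModelSpec:
    """What to adjust for and how to treat relatedness."""

    covariates: tuple = DEFAULT_COVARIATES
    interaction: str | None = None  # covariate crossed with the exposure
    random_effect: bool = True
    extra_covariates: pd.DataFrame | None = None  # e.g. methylome PCs, samples x k
    model_tag: str = "primary"

    def __post_init__(self) -> None:
        if self.interaction is not None and self.interaction not in self.covariates:
            raise ValueError(
                f"interaction covariate {self.interaction!r} must be in covariates"
            )


@dataclass
class SiteResult:
    probe_id: str
    coefficient: float
    se: float
    p_value: float
    converged: bool
    sigma_sibship: float
    sigma_resid: float
    n_used: int


def ln_transform_crp(crp) -> np.ndarray:
    """Natural log of serum CRP (mg/L); CRP must be strictly positive."""
    arr = np.asarray(crp, dtype=float)
    if (arr <= 0).any():
        idx = np.nonzero(arr <= 0)[0]
        if hasattr(crp, "index"):
            raise ValueError(f"non-positive CRP for sample {crp.index[idx[0]]!r}")
        raise ValueError(f"non-positive CRP at position {idx[0]}")
    return np.log(arr)


def build_covariate_matrix(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Numeric covariate columns per the model spec (sex coded F=0, M=1)."""
    cols = {}
    for c in spec.covariates:
        if c == "sex":
            cols["sex"] = (cohort["sex"] == "M").astype(float).to_numpy()
        elif c in ("current_smoker", "hypertension"):
            cols[c] = cohort[c].astype(float).to_numpy()
        else:
            cols[c] = cohort[c].astype(float).to_numpy()
    out = pd.DataFrame(cols, index=cohort["sample_id"])
    if spec.extra_covariates is not None:
        extra = spec.extra_covariates.loc[out.index]
        out = pd.concat([out, extra], axis=1)
    return out


# ---------------------------------------------------------------------------
# REML core for the random-intercept model


class _GroupData:
    """Precomputed group bookkeeping shared across all sites of a scan."""

    def __init__(self, sibship_ids) -> None:
        codes, uniques = pd.factorize(np.asarray(sibship_ids))
        self.codes = codes
        self.n_groups = len(uniques)
        self.sizes = np.bincount(codes, minlength=self.n_groups).astype(float)
        self.max_size = int(self.sizes.max()) if self.n_groups else 0

    def group_sums(self, mat: np.ndarray) -> np.ndarray:
        """Column sums of ``mat`` (n x p) within each group -> (G x p)."""
        out = np.zeros((self.n_groups, mat.shape[1]))
        np.add.at(out, self.codes, mat)
        return out


def _reml_neg2loglik(theta, xtx, xty, yty, s_x, s_y, sizes, n, p):
    """-2 * restricted log-likelihood, profiled over beta and sigma_res."""
    c = theta / (1.0 + sizes * theta)  # per-group Woodbury weight
    a_mat = xtx - np.einsum("g,gi,gj->ij", c, s_x, s_x)
    b_vec = xty - (c * s_y) @ s_x
    q_val = yty - np.dot(c, s_y**2)
    sign, logdet_a = np.linalg.slogdet(a_mat)
    if sign <= 0:
        return np.inf
    try:
        beta = np.linalg.solve(a_mat, b_vec)
    except np.linalg.LinAlgError:
        return np.inf
    rss = q_val - b_vec @ beta
    if rss <= 0:
        return np.inf
    logdet_sigma = np.log1p(sizes * theta).sum()
    return logdet_sigma + logdet_a + (n - p) * np.log(rss)


def _fit_reml(y, x_mat, groups: _GroupData):
    """REML fit of the random-intercept model; returns estimates or None."""
    n, p = x_mat.shape
    xtx = x_mat.T @ x_mat
    xty = x_mat.T @ y
    yty = float(y @ y)
    s_x = groups.group_sums(x_mat)
    s_y = groups.group_sums(y[:, None]).ravel()
    sizes = groups.sizes

    def obj(log_theta):
        return _reml_neg2loglik(
            np.exp(log_theta), xtx, xty, yty, s_x, s_y, sizes, n, p
        )

    res = optimize.minimize_scalar(
        obj, bounds=(np.log(1e-8), np.log(1e4)), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        return None
    theta = float(np.exp(res.x))
    # compare against the theta -> 0 boundary (independence)
    at_zero = _reml_neg2loglik(0.0, xtx, xty, yty, s_x, s_y, sizes, n, p)
    if at_zero <= res.fun:
        theta = 0.0

    c = theta / (1.0 + sizes * theta)
    a_mat = xtx - np.einsum("g,gi,gj->ij", c, s_x, s_x)
    b_vec = xty - (c * s_y) @ s_x
    q_val = yty - np.dot(c, s_y**2)
    beta = np.linalg.solve(a_mat, b_vec)
    rss = q_val - b_vec @ beta
    sigma2_res = rss / (n - p)
    cov_beta = sigma2_res * np.linalg.inv(a_mat)
    return {
        "beta": beta,
        "cov_beta": cov_beta,
        "sigma2_sib": theta * sigma2_res,
        "sigma2_res": sigma2_res,
        "theta": theta,
    }


def _ols_site(y, x_mat):
    """OLS with t-based p-values, via statsmodels."""
    fit = sm.OLS(y, x_mat).fit()
    return fit


def _assemble_design(x, cov_mat, interaction_col=None):
    n = x.shape[0]
    pieces = [np.ones(n), x]
    names = ["intercept", "exposure"]
    if cov_mat is not None and cov_mat.shape[1]:
        pieces.append(cov_mat)
        names += [f"c{i}" for i in range(cov_mat.shape[1])]
    if interaction_col is not None:
        pieces.append(x * interaction_col)
        names.append("interaction")
    x_mat = np.column_stack(pieces)
    return x_mat, names


def fit_site_lmm(
    y,
    x,
    covariates=None,
    sibship_ids=None,
    probe_id: str = "",
    groups: _GroupData | None = None,
    interaction_col=None,
    test_term: str = "exposure",
) -> SiteResult:
    """Fit one site: random-intercept REML with OLS fallback.

    Parameters are plain vectors/matrices; ``groups`` may carry precomputed
    sibship bookkeeping when scanning many sites.  ``test_term`` selects the
    coefficient reported ("exposure" or "interaction").
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateExposureError(f"constant exposure at site {probe_id!r}")
    cov_mat = None if covariates is None else np.asarray(covariates, dtype=float)
    x_mat, names = _assemble_design(x, cov_mat, interaction_col)
    term_idx = names.index("interaction" if test_term == "interaction" else "exposure")
    n = y.size

    if groups is None:
        if sibship_ids is None:
            raise ValueError("need sibship_ids or a precomputed _GroupData")
        groups = _GroupData(sibship_ids)
    if groups.n_groups < 2:
        raise ValueError("need at least 2 sibships")

    use_ols = groups.max_size <= 1
    fit = None
    if not use_ols:
        fit = _fit_reml(y, x_mat, groups)
    if fit is None or fit["theta"] == 0.0:
        ols = _ols_site(y, x_mat)
        return SiteResult(
            probe_id=probe_id,
            coefficient=float(ols.params[term_idx]),
            se=float(ols.bse[term_idx]),
            p_value=float(ols.pvalues[term_idx]),
            converged=fit is not None or use_ols,
            sigma_sibship=0.0,
            sigma_resid=float(ols.scale),
            n_used=n,
        )
    coef = float(fit["beta"][term_idx])
    se = float(np.sqrt(fit["cov_beta"][term_idx, term_idx]))
    z = coef / se
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return SiteResult(
        probe_id=probe_id,
        coefficient=coef,
        se=se,
        p_value=max(p, np.finfo(float).tiny),
        converged=True,
        sigma_sibship=float(fit["sigma2_sib"]),
        sigma_resid=float(fit["sigma2_res"]),
        n_used=n,
    )


def run_ewas(
    beta,
    cohort: pd.DataFrame,
    spec: ModelSpec | None = None,
    probes=None,
) -> pd.DataFrame:
    """Scan every kept probe; per-site failures are logged, never fatal.

    ``beta`` is a BetaMatrix or a probes x samples DataFrame aligned to
    ``cohort.sample_id``.  Returns an association table sorted as input,
    one row per successfully fitted probe.
    """
    spec = spec or ModelSpec()
    bdf = beta.values if hasattr(beta, "values") and not isinstance(beta, pd.DataFrame) else beta
    if isinstance(bdf, np.ndarray):
        raise TypeError("beta must be a BetaMatrix or DataFrame with probe index")
    bdf = bdf.loc[:, cohort["sample_id"]]
    if probes is not None:
        bdf = bdf.loc[probes]
    y = ln_transform_crp(cohort.set_index("sample_id")["crp"])
    cov = build_covariate_matrix(cohort, spec).to_numpy()
    groups = _GroupData(cohort["sibship_id"]) if spec.random_effect else None
    inter = None
    if spec.interaction is not None:
        inter = build_covariate_matrix(cohort, spec)[spec.interaction].to_numpy()

    rows = []
    vals = bdf.to_numpy(dtype=float)
    if not spec.random_effect:
        sing = _GroupData(np.arange(len(cohort)))
    for i, pid in enumerate(bdf.index):
        if i and i % 1000 == 0:
            log.info("ewas: %d/%d probes", i, len(bdf))
        try:
            r = fit_site_lmm(
                y,
                vals[i],
                covariates=cov,
                probe_id=pid,
                groups=groups if spec.random_effect else sing,
                interaction_col=inter,
                test_term="interaction" if spec.interaction else "exposure",
            )
        except DegenerateExposureError as exc:
            log.warning("skipping site: %s", exc)
            continue
        rows.append(
            (pid, r.coefficient, r.se, r.p_value, r.converged,
             r.sigma_sibship, r.sigma_resid, r.n_used, spec.model_tag)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id", "coefficient", "se", "p_value", "converged",
            "sigma_sibship", "sigma_resid", "n_used", "model_tag",
        ],
    )


def fit_interaction(
    beta, cohort: pd.DataFrame, probes, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """Sex-by-methylation interaction Wald test on a probe subset.

    Run on the significant sites from the primary scan; the random effect is
    retained.  Returns the interaction coefficient and p per probe.
    """
    if cohort["sex"].nunique() < 2:
        raise ValueError("interaction model needs both sexes in the cohort")
    base = spec or ModelSpec()
    ispec = ModelSpec(
        covariates=base.covariates,
        interaction="sex",
        random_effect=base.random_effect,
        extra_covariates=base.extra_covariates,
        model_tag="interaction",
    )
    return run_ewas(beta, cohort, ispec, probes=probes)


def count_direction(table: pd.DataFrame, significant) -> tuple[int, int, float]:
    """Count inverse (negative-coefficient) associations among significant
    sites; returns (n_negative, n_total, percent rounded to 1 decimal)."""
    sig = list(significant)
    if not sig:
        raise ValueError("significant set is empty")
    sub = table.set_index("probe_id").loc[sig]
    n_neg = int((sub["coefficient"] < 0).sum())
    n_tot = len(sub)
    return n_neg, n_tot, round(100.0 * n_neg / n_tot, 1)
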