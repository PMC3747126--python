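"""Mixed-model association: oracle agreement, recovery, scan bookkeeping."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from sibewas.association import (
    DegenerateExposureError,
    ModelSpec,
    _GroupData,
    count_direction,
    fit_interaction,
    fit_site_lmm,
    ln_transform_crp,
    run_ewas,
)

warnings.filterwarnings("ignore")


def _sib_cohort(rng, n_sib=450, max_size=4):
    sizes = rng.choice(np.arange(1, max_size + 1), size=n_sib,
                       p=[0.4, 0.35, 0.15, 0.1][: max_size])
    return np.repeat(np.arange(n_sib), sizes)


def _simulate_site(rng, groups, coef, sib_sd=0.45, res_sd=1.0):
    n = groups.size
    x = rng.beta(4, 4, n) * 0.3 + 0.3
    b = rng.normal(0, sib_sd, groups.max() + 1)
    y = 0.5 + coef * x + b[groups] + rng.normal(0, res_sd, n)
    return y, x


class TestLnTransform:
    @pytest.mark.parametrize(
        "crp, expected", [(1.0, 0.0), (np.e, 1.0), (0.38, -0.9676)]
    )
    def test_values(self, crp, expected):
        assert ln_transform_crp([crp])[0] == pytest.approx(expected, abs=1e-4)

    def test_nonpositive_crp_names_sample(self):
        s = pd.Series([1.0, -2.0], index=["good", "bad"])
        with pytest.raises(ValueError, match="bad"):
            ln_transform_crp(s)


class TestSiteFit:
    def test_matches_statsmodels_mixedlm(self, rng):
        """REML estimates agree with the statsmodels mixed-model oracle."""
        groups = _sib_cohort(rng)
        y, x = _simulate_site(rng, groups, coef=-3.0)
        cov = np.column_stack([rng.normal(66, 7, groups.size), rng.integers(0, 2, groups.size)])
        mine = fit_site_lmm(y, x, covariates=cov, sibship_ids=groups)
        design = np.column_stack([np.ones(groups.size), x, cov])
        oracle = sm.MixedLM(y, design, groups=groups).fit(reml=True)
        assert mine.coefficient == pytest.approx(oracle.params[1], rel=1e-3, abs=1e-3)
        assert mine.se == pytest.approx(oracle.bse[1], rel=2e-2)
        assert mine.sigma_sibship == pytest.approx(
            float(np.asarray(oracle.cov_re)[0, 0]), rel=0.05, abs=0.01
        )
        assert mine.sigma_resid == pytest.approx(oracle.scale, rel=0.05)

    def test_singleton_cohort_equals_ols(self, rng):
        """With every sibship a singleton the fit is exactly OLS."""
        n = 300
        groups = np.arange(n)
        y, x = _simulate_site(rng, groups, coef=-2.0, sib_sd=0.0)
        cov = rng.normal(0, 1, (n, 2))
        mine = fit_site_lmm(y, x, covariates=cov, sibship_ids=groups)
        design = np.column_stack([np.ones(n), x, cov])
        ols = sm.OLS(y, design).fit()
        assert mine.coefficient == pytest.approx(ols.params[1], rel=1e-6)
        assert mine.se == pytest.approx(ols.bse[1], rel=1e-6)
        assert mine.p_value == pytest.approx(ols.pvalues[1], rel=1e-6)
        assert mine.sigma_sibship == 0.0

    def test_parameter_recovery_unbiased(self, rng):
        """Mean estimate over 200 simulated cohorts within 5% of the planted
        coefficient (-3.0) at the study's n and noise scale."""
        estimates = []
        for _ in range(200):
            groups = _sib_cohort(rng)
            y, x = _simulate_site(rng, groups, coef=-3.0)
            gd = _GroupData(groups)
            estimates.append(fit_site_lmm(y, x, groups=gd).coefficient)
        assert np.mean(estimates) == pytest.approx(-3.0, abs=0.15)

    def test_constant_exposure_raises(self, rng):
        groups = _sib_cohort(rng, n_sib=20)
        y = rng.normal(0, 1, groups.size)
        with pytest.raises(DegenerateExposureError):
            fit_site_lmm(y, np.full(groups.size, 0.5), sibship_ids=groups)

    def test_coefficient_sign_matches_partial_correlation(self, rng):
        """Sign of the exposure estimate equals the sign of the partial
        correlation of x with y given covariates (small brute-force case)."""
        n = 60
        groups = np.repeat(np.arange(30), 2)
        cov = rng.normal(0, 1, (n, 1))
        x = rng.normal(0, 1, n) + cov[:, 0]
        y = 0.8 * x - 2.0 * cov[:, 0] + rng.normal(0, 1, n)
        r = fit_site_lmm(y, x, covariates=cov, sibship_ids=groups)
        # residualize both on covariates, correlate
        p = np.column_stack([np.ones(n), cov])
        rx = x - p @ np.linalg.lstsq(p, x, rcond=None)[0]
        ry = y - p @ np.linalg.lstsq(p, y, rcond=None)[0]
        assert np.sign(r.coefficient) == np.sign(np.corrcoef(rx, ry)[0, 1])


class TestEwasScan:
    def _beta_df(self, rng, cohort, n_probes):
        return pd.DataFrame(
            rng.beta(4, 6, (n_probes, len(cohort))) ,
            index=[f"p{i}" for i in range(n_probes)],
            columns=cohort["sample_id"],
        )

    def _cohort(self, rng, n=200):
        groups = _sib_cohort(rng, n_sib=n)
        m = groups.size
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(m)],
                "sibship_id": [f"f{g}" for g in groups],
                "age": rng.normal(66, 7, m),
                "sex": rng.choice(["F", "M"], m),
                "bmi": rng.normal(31, 6, m),
                "current_smoker": rng.random(m) < 0.1,
                "hypertension": rng.random(m) < 0.8,
                "crp": rng.lognormal(-1, 1, m),
            }
        )

    def test_degenerate_probe_skipped_not_fatal(self, rng):
        cohort = self._cohort(rng)
        beta = self._beta_df(rng, cohort, 10)
        beta.iloc[3] = 0.5  # constant
        table = run_ewas(beta, cohort)
        assert len(table) == 9
        assert "p3" not in set(table["probe_id"])

    def test_duplicate_probes_give_identical_rows(self, rng):
        cohort = self._cohort(rng)
        beta = self._beta_df(rng, cohort, 3)
        beta.iloc[2] = beta.iloc[0].values
        table = run_ewas(beta, cohort).set_index("probe_id")
        assert table.loc["p2", "coefficient"] == table.loc["p0", "coefficient"]
        assert table.loc["p2", "p_value"] == table.loc["p0", "p_value"]

    def test_sample_order_invariance(self, rng):
        cohort = self._cohort(rng)
        beta = self._beta_df(rng, cohort, 5)
        t1 = run_ewas(beta, cohort)
        perm = cohort.sample(frac=1, random_state=1).reset_index(drop=True)
        t2 = run_ewas(beta, perm)
        np.testing.assert_allclose(
            t1["coefficient"].values, t2["coefficient"].values, rtol=1e-8
        )

    def test_planted_sites_outrank_null(self, study_dataset):
        """Planted effects (|coef| >= 3) rank above every null probe."""
        from sibewas.normalization import normalize_pipeline

        ds = study_dataset
        beta, _ = normalize_pipeline(ds.intensities, ds.controls)
        table = run_ewas(beta.values, ds.cohort).sort_values("p_value")
        top = set(table["probe_id"].head(3))
        assert top == set(ds.truth_effects["probe_id"])


class TestInteraction:
    def test_no_interaction_generated_none_detected(self, rng):
        groups = _sib_cohort(rng, n_sib=300)
        n = groups.size
        cohort = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "sibship_id": [f"f{g}" for g in groups],
                "age": rng.normal(66, 7, n),
                "sex": rng.choice(["F", "M"], n, p=[0.7, 0.3]),
                "bmi": rng.normal(31, 6, n),
                "current_smoker": rng.random(n) < 0.1,
                "hypertension": rng.random(n) < 0.8,
                "crp": rng.lognormal(-1, 1, n),
            }
        )
        beta = pd.DataFrame(
            rng.beta(4, 6, (20, n)),
            index=[f"p{i}" for i in range(20)],
            columns=cohort["sample_id"],
        )
        table = fit_interaction(beta, cohort, probes=[f"p{i}" for i in range(20)])
        assert (table["model_tag"] == "interaction").all()
        # family-wise control: no interaction p below 0.05/20
        assert (table["p_value"] > 0.05 / 20).all()

    def test_planted_sex_specific_effect_detected(self, rng):
        groups = _sib_cohort(rng, n_sib=460)
        n = groups.size
        sex = rng.choice(["F", "M"], n)
        x = rng.beta(2, 2, n) * 0.6 + 0.2
        # effect differs by 4 between the sexes
        coef = np.where(sex == "M", -4.0, 0.0)
        b = rng.normal(0, 0.45, groups.max() + 1)
        y = coef * x + b[groups] + rng.normal(0, 1, n)
        cohort = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "sibship_id": [f"f{g}" for g in groups],
                "age": rng.normal(66, 7, n),
                "sex": sex,
                "bmi": rng.normal(31, 6, n),
                "current_smoker": rng.random(n) < 0.1,
                "hypertension": rng.random(n) < 0.8,
                "crp": np.exp(y),
            }
        )
        beta = pd.DataFrame(x[None, :], index=["hit"], columns=cohort["sample_id"])
        table = fit_interaction(beta, cohort, probes=["hit"])
        assert table["p_value"].iloc[0] < 0.05 / 257

    def test_single_sex_cohort_rejected(self, rng):
        cohort = TestEwasScan()._cohort(rng)
        cohort["sex"] = "F"
        beta = pd.DataFrame(
            rng.beta(4, 6, (2, len(cohort))),
            index=["p0", "p1"],
            columns=cohort["sample_id"],
        )
        with pytest.raises(ValueError, match="both sexes"):
            fit_interaction(beta, cohort, probes=["p0"])


class TestDirection:
    def test_study_arithmetic(self):
        table = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(257)],
                "coefficient": [-1.0] * 207 + [1.0] * 50,
            }
        )
        n_neg, n_tot, pct = count_direction(table, table["probe_id"])
        assert (n_neg, n_tot, pct) == (207, 257, 80.5)

    @pytest.mark.parametrize(
        "coefs, expected", [([-1, -2, -3], 100.0), ([-1, 1, 1], 33.3)]
    )
    def test_rounding(self, coefs, expected):
        table = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(len(coefs))], "coefficient": coefs}
        )
        assert count_direction(table, table["probe_id"])[2] == expected

    def test_empty_set_rejected(self):
        table = pd.DataFrame({"probe_id": ["p0"], "coefficient": [1.0]})
        with pytest.raises(ValueError):
            count_direction(table, [])
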