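"""Control-probe normalization and beta-value computation."""

import numpy as np
import pandas as pd
import pytest

from sibewas.datatypes import IntensityPair
from sibewas.normalization import (
    compute_beta,
    normalize_pipeline,
    orthogonalize_controls,
    regress_out_controls,
)


class TestControlPCA:
    def test_scores_orthogonal(self, rng):
        controls = pd.DataFrame(rng.normal(1000, 50, (56, 80)))
        pca = orthogonalize_controls(controls, k=5)
        gram = pca.component_scores.T @ pca.component_scores
        off = gram.values - np.diag(np.diag(gram.values))
        assert np.abs(off).max() < 1e-8

    def test_single_chip_direction_recovered(self, study_dataset):
        """PC1 of the controls tracks the planted chip effect."""
        pca = orthogonalize_controls(study_dataset.controls, k=2)
        chip_effect = study_dataset.chip_assignment.to_numpy()
        # correlate PC1 scores with the per-sample chip shift realisations
        shifts = (
            np.log(study_dataset.controls).mean(axis=0).to_numpy()
        )  # mean log control level per sample ~ chip shift
        r = np.corrcoef(pca.component_scores.iloc[:, 0], shifts)[0, 1]
        assert abs(r) > 0.99
        assert chip_effect.shape == shifts.shape

    def test_rank_and_degenerate_guards(self, rng):
        controls = pd.DataFrame(rng.normal(0, 1, (5, 8)))
        with pytest.raises(ValueError):
            orthogonalize_controls(controls, k=50)
        with pytest.raises(ValueError):
            orthogonalize_controls(pd.DataFrame(np.ones((5, 8))), k=1)
        with pytest.raises(ValueError):
            orthogonalize_controls(controls, k=0)

    def test_kaiser_rule_default(self, study_dataset):
        pca = orthogonalize_controls(study_dataset.controls)
        assert 1 <= pca.k <= 56
        assert (pca.explained_variance > 1.0).all()


def _chip_variance_component(pair, chips):
    """Average one-way ANOVA between-chip variance component of log M."""
    logm = np.log(pair.methylated.to_numpy() + 1.0)
    labels = np.unique(chips)
    n = chips.size
    sizes = np.array([(chips == c).sum() for c in labels])
    grand = logm.mean(axis=1)
    bss = sum(
        s * (logm[:, chips == c].mean(axis=1) - grand) ** 2
        for c, s in zip(labels, sizes)
    )
    wss = sum(
        ((logm[:, chips == c] - logm[:, chips == c].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        for c in labels
    )
    bms = bss / (labels.size - 1)
    wms = wss / (n - labels.size)
    n_bar = (n - (sizes**2).sum() / n) / (labels.size - 1)
    return float(np.maximum((bms - wms) / n_bar, 0.0).mean())


class TestRegression:
    def test_residuals_uncorrelated_with_scores(self, study_dataset):
        pca = orthogonalize_controls(study_dataset.controls, k=3)
        out = regress_out_controls(study_dataset.intensities, pca)
        logm = np.log(out.methylated.to_numpy() + 1.0)
        logm = logm - logm.mean(axis=1, keepdims=True)
        scores = pca.component_scores.to_numpy()
        scores = scores / np.linalg.norm(scores, axis=0)
        proj = np.abs(logm @ scores) / (np.linalg.norm(logm, axis=1, keepdims=True) + 1e-30)
        assert proj.max() < 1e-6

    def test_idempotent(self, study_dataset):
        pca = orthogonalize_controls(study_dataset.controls, k=3)
        once = regress_out_controls(study_dataset.intensities, pca)
        twice = regress_out_controls(once, pca)
        a = once.methylated.to_numpy()
        b = twice.methylated.to_numpy()
        assert np.max(np.abs(a - b) / (np.abs(a) + 1.0)) < 1e-6

    def test_chip_variance_removed(self, study_dataset):
        """Between-chip variance of log-intensities drops >=90%."""
        ds = study_dataset
        pca = orthogonalize_controls(ds.controls)
        cleaned = regress_out_controls(ds.intensities, pca)
        chips = ds.chip_assignment.to_numpy()

        raw = _chip_variance_component(ds.intensities, chips)
        norm = _chip_variance_component(cleaned, chips)
        assert norm < 0.10 * raw

    def test_sample_count_guard(self, rng):
        controls = pd.DataFrame(rng.normal(0, 1, (56, 5)))
        pca = orthogonalize_controls(controls, k=4)
        m = pd.DataFrame(rng.lognormal(7, 1, (3, 5)), columns=controls.columns)
        pair = IntensityPair(m, m)
        with pytest.raises(ValueError):
            regress_out_controls(pair, pca)


class TestBeta:
    @pytest.mark.parametrize(
        "m, u, alpha, expected",
        [
            (0.0, 0.0, 100.0, 0.0),
            (900.0, 0.0, 100.0, 0.9),
            (500.0, 500.0, 0.0, 0.5),
        ],
    )
    def test_closed_forms(self, m, u, alpha, expected):
        pair = IntensityPair(
            pd.DataFrame([[m]], index=["p"], columns=["s"]),
            pd.DataFrame([[u]], index=["p"], columns=["s"]),
        )
        assert compute_beta(pair, alpha=alpha).values.iloc[0, 0] == pytest.approx(
            expected
        )

    def test_monotone_in_channels(self, rng):
        u = rng.uniform(0, 1000, 50)
        m_grid = np.linspace(0, 2000, 40)
        for ui in u[:5]:
            pair = IntensityPair(
                pd.DataFrame(m_grid[None, :], index=["p"]),
                pd.DataFrame(np.full((1, 40), ui), index=["p"]),
            )
            vals = compute_beta(pair).values.iloc[0].to_numpy()
            assert (np.diff(vals) > 0).all()  # increasing in M

    def test_negative_alpha_rejected(self, study_dataset):
        with pytest.raises(ValueError):
            compute_beta(study_dataset.intensities, alpha=-1)

    def test_values_in_unit_interval(self, study_dataset):
        beta, _ = normalize_pipeline(study_dataset.intensities, study_dataset.controls)
        v = beta.values.to_numpy()
        assert v.min() >= 0 and v.max() <= 1
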