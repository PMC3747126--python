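"""Synthetic cohort generator emulating a sibship-based methylation study.

The generator produces everything the analysis pipeline consumes: an
Infinium-style methylated/unmethylated intensity pair, a 56-feature control
probe matrix sharing chip effects with the targets, a probe manifest with
exclusion flags, and a phenotype table with sibship structure, so every
downstream stage is testable without external data.

Defaults mirror the study design the pipeline targets: ~500 sibships of
sizes 1-10 averaging ~1.96 members (about 40% singletons), participants in
their mid-60s, ~71% female, BMI higher in women, ~80% hypertensive, serum
CRP log-normal with a higher female median (0.38 vs 0.27 mg/L).  Planted
structure — negative methylation effects on ln CRP at known sites,
bimodal probes, and low-quality samples displaced on the control probes —
is returned as ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import IntensityPair
from . import io as sio


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


#: Sibship size distribution over 1..10: 40.2% singletons (198/492), with a
#: truncated-geometric tail calibrated so the mean size is 966/492 = 1.96.
DEFAULT_SIBSHIP_SIZE_PROBS = (
    0.402439,
    0.370357,
    0.140855,
    0.053570,
    0.020374,
    0.007749,
    0.002947,
    0.001121,
    0.000426,
    0.000162,
)

#: Phenotype distribution parameters: female/male means and SDs.
DEFAULT_PHENO_PARAMS = {
    "female_fraction": 0.709,
    "age_mean_f": 66.10,
    "age_sd_f": 7.56,
    "age_mean_m": 66.70,
    "age_sd_m": 7.64,
    "bmi_mean_f": 32.06,
    "bmi_sd_f": 6.58,
    "bmi_mean_m": 28.98,
    "bmi_sd_m": 4.81,
    "smoker_fraction": 0.10,
    "hypertensive_fraction_f": 0.835,
    "hypertensive_fraction_m": 0.801,
}

#: ln-CRP linear model.  Sex-specific intercepts equal the log of the sex
#: medians (0.38 / 0.27 mg/L); age and BMI enter centred, so the intercepts
#: set the medians directly.  The total ln-scale SD (~1.1, matching the
#: quartile spread) splits into a sibship random intercept and a residual.
DEFAULT_CRP_MODEL = {
    "intercept_f": -0.9676,  # ln 0.38
    "intercept_m": -1.3093,  # ln 0.27
    "age_coef": 0.005,
    "bmi_coef": 0.03,
    "smoker_coef": 0.30,
    "sibship_sd": 0.45,
    "residual_sd": 1.0,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the emulated study design."""

    n_sibships: int = 492
    sibship_size_probs: tuple = DEFAULT_SIBSHIP_SIZE_PROBS
    n_probes: int = 2000
    n_control_probes: int = 56
    chip_size: int = 12
    chip_effect_sd: float = 0.15  # additive on the log-intensity scale
    pheno_params: dict = field(default_factory=lambda: dict(DEFAULT_PHENO_PARAMS))
    crp_model: dict = field(default_factory=lambda: dict(DEFAULT_CRP_MODEL))
    planted_effects: tuple = ()  # (probe index, lnCRP per unit beta-value)
    n_multimodal_probes: int = 0
    n_bad_samples: int = 0
    bad_sample_displacement_sd: float = 6.0
    n_xy_probes: int = 0
    n_crossreactive: int = 0
    n_snp_overlap: int = 0
    base_intensity: float = 4000.0
    intensity_log_sd: float = 0.3
    common_log_sd: float = 0.12  # per-observation brightness, shared by channels
    noise_log_sd: float = 0.03  # channel-specific measurement noise
    beta_within_sd: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        probs = np.asarray(self.sibship_size_probs, dtype=float)
        if probs.size != 10 or (probs < 0).any() or abs(probs.sum() - 1) > 1e-6:
            raise ConfigurationError(
                "sibship_size_probs must be 10 non-negative values summing to 1"
            )
        for name in (
            "n_sibships",
            "n_probes",
            "n_control_probes",
            "n_multimodal_probes",
            "n_bad_samples",
            "n_xy_probes",
            "n_crossreactive",
            "n_snp_overlap",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        idx = [i for i, _ in self.planted_effects]
        if len(set(idx)) != len(idx):
            raise ConfigurationError("planted effect probe indices must be distinct")
        if idx and (min(idx) < 0 or max(idx) >= self.n_probes):
            raise ConfigurationError("planted effect index outside [0, n_probes)")
        if self.chip_effect_sd < 0 or self.chip_size < 1:
            raise ConfigurationError("invalid chip parameters")


@dataclass
class SyntheticDataset:
    """A complete simulated study with its generating truth."""

    intensities: IntensityPair
    controls: pd.DataFrame
    manifest: pd.DataFrame
    cohort: pd.DataFrame
    beta_true: pd.DataFrame  # latent beta-values the intensities encode
    truth_effects: pd.DataFrame  # columns: probe_id, coefficient
    truth_multimodal: list
    truth_bad_samples: list
    sibship_intercepts: pd.Series
    chip_assignment: pd.Series
    config: SimulationConfig = None


def simulate_cohort(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset; byte-identical for a fixed seed.

    ln CRP follows a linear model in age, sex, BMI, smoking and the planted
    probes' beta-values, plus a sibship random intercept and residual noise.
    Intensities carry an additive per-chip effect on the log scale shared
    with the control probes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    cohort, sib_intercepts = _simulate_pedigree_phenotypes(config, rng)
    n_samples = len(cohort)
    sample_ids = cohort["sample_id"].to_numpy()

    manifest, mm_idx = _simulate_manifest(config, rng)
    beta = _simulate_beta(config, rng, n_samples, mm_idx)

    # ln CRP: covariate part was already drawn in cohort (as linear predictor
    # without methylation); add the planted methylation effects.
    lncrp = cohort.pop("_lncrp_base").to_numpy()
    # methylation effects enter centred so the intercepts keep setting the
    # CRP medians regardless of how many effects are planted
    for probe_idx, coef in config.planted_effects:
        lncrp = lncrp + coef * (beta[probe_idx] - beta[probe_idx].mean())
    cohort["crp"] = np.exp(lncrp)

    chips = pd.Series(
        np.arange(n_samples) // config.chip_size, index=sample_ids, name="chip"
    )
    chip_effects = rng.normal(0.0, config.chip_effect_sd, int(chips.max()) + 1)
    sample_shift = chip_effects[chips.to_numpy()]

    m_int, u_int = _beta_to_intensities(config, rng, beta, sample_shift)
    controls = _simulate_controls(config, rng, n_samples, sample_shift)

    bad_samples = []
    if config.n_bad_samples > 0:
        if config.n_bad_samples > n_samples:
            raise ConfigurationError("n_bad_samples exceeds cohort size")
        bad_pos = rng.choice(n_samples, size=config.n_bad_samples, replace=False)
        bad_samples = [sample_ids[i] for i in sorted(bad_pos)]
        # displace a third of the control features far beyond the QC cut
        n_feat = max(1, config.n_control_probes // 3)
        sds = controls.std(axis=1, ddof=1).to_numpy()
        for s in bad_samples:
            feats = rng.choice(config.n_control_probes, size=n_feat, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_feat)
            controls.iloc[feats, controls.columns.get_loc(s)] += (
                signs * config.bad_sample_displacement_sd * sds[feats]
            )

    probe_ids = manifest["probe_id"].to_numpy()
    pair = IntensityPair(
        pd.DataFrame(m_int, index=probe_ids, columns=sample_ids),
        pd.DataFrame(u_int, index=probe_ids, columns=sample_ids),
    )
    truth_effects = pd.DataFrame(
        [(probe_ids[i], c) for i, c in config.planted_effects],
        columns=["probe_id", "coefficient"],
    )
    return SyntheticDataset(
        intensities=pair,
        controls=controls,
        manifest=manifest,
        cohort=cohort,
        beta_true=pd.DataFrame(beta, index=probe_ids, columns=sample_ids),
        truth_effects=truth_effects,
        truth_multimodal=[probe_ids[i] for i in mm_idx],
        truth_bad_samples=bad_samples,
        sibship_intercepts=sib_intercepts,
        chip_assignment=chips,
        config=replace(config),
    )


def _simulate_pedigree_phenotypes(config, rng):
    sizes = rng.choice(
        np.arange(1, 11), size=config.n_sibships, p=config.sibship_size_probs
    )
    sib_ids = [f"sib{j:05d}" for j in range(config.n_sibships)]
    sib_of_sample = np.repeat(np.arange(config.n_sibships), sizes)
    n = sib_of_sample.size
    p = config.pheno_params
    cm = config.crp_model

    female = rng.random(n) < p["female_fraction"]
    age = np.where(
        female,
        rng.normal(p["age_mean_f"], p["age_sd_f"], n),
        rng.normal(p["age_mean_m"], p["age_sd_m"], n),
    )
    bmi = np.where(
        female,
        rng.normal(p["bmi_mean_f"], p["bmi_sd_f"], n),
        rng.normal(p["bmi_mean_m"], p["bmi_sd_m"], n),
    )
    smoker = rng.random(n) < p["smoker_fraction"]
    htn = rng.random(n) < np.where(
        female, p["hypertensive_fraction_f"], p["hypertensive_fraction_m"]
    )

    sib_intercepts = pd.Series(
        rng.normal(0.0, cm["sibship_sd"], config.n_sibships), index=sib_ids
    )
    age_c = age - np.where(female, p["age_mean_f"], p["age_mean_m"])
    bmi_c = bmi - np.where(female, p["bmi_mean_f"], p["bmi_mean_m"])
    lncrp = (
        np.where(female, cm["intercept_f"], cm["intercept_m"])
        + cm["age_coef"] * age_c
        + cm["bmi_coef"] * bmi_c
        + cm["smoker_coef"] * smoker
        + sib_intercepts.to_numpy()[sib_of_sample]
        + rng.normal(0.0, cm["residual_sd"], n)
    )
    cohort = pd.DataFrame(
        {
            "sample_id": [f"s{j:05d}" for j in range(n)],
            "sibship_id": [sib_ids[j] for j in sib_of_sample],
            "age": np.round(age, 2),
            "sex": np.where(female, "F", "M"),
            "bmi": np.round(bmi, 2),
            "current_smoker": smoker,
            "hypertension": htn,
            "_lncrp_base": lncrp,
        }
    )
    return cohort, sib_intercepts


def _simulate_manifest(config, rng):
    npr = config.n_probes
    probe_ids = [f"cg{j:07d}" for j in range(npr)]
    # reserve the first indices for planted effects etc.; XY probes must not
    # collide with planted-effect or multimodal probes
    planted = {i for i, _ in config.planted_effects}
    free = [i for i in range(npr) if i not in planted]
    rng.shuffle(free)
    need = config.n_multimodal_probes + config.n_xy_probes
    if need > len(free):
        raise ConfigurationError("not enough probes for multimodal + XY assignment")
    mm_idx = sorted(free[: config.n_multimodal_probes])
    xy_idx = sorted(
        free[config.n_multimodal_probes : config.n_multimodal_probes + config.n_xy_probes]
    )
    xy_set = set(xy_idx)

    chrom = rng.choice([str(c) for c in range(1, 23)], size=npr)
    chrom[xy_idx] = rng.choice(["X", "Y"], size=len(xy_idx))
    cross = np.zeros(npr, dtype=bool)
    snp = np.zeros(npr, dtype=bool)
    flaggable = [i for i in range(npr) if i not in xy_set]
    rng.shuffle(flaggable)
    cross[flaggable[: config.n_crossreactive]] = True
    snp_pool = flaggable[config.n_crossreactive :] + flaggable[: config.n_crossreactive]
    snp[snp_pool[: config.n_snp_overlap]] = True

    genes = [f"GENE{j // 2:05d}" for j in range(npr)]  # ~2 probes per gene
    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chrom,
            "position": rng.integers(10_000, 200_000_000, size=npr),
            "strand": rng.choice(["+", "-"], size=npr),
            "gene": genes,
            "crossreactive_flag": cross,
            "snp_overlap_flag": snp,
        }
    )
    return manifest, mm_idx


def _simulate_beta(config, rng, n_samples, mm_idx):
    from scipy.special import expit, logit

    npr = config.n_probes
    # probe-level mean methylation: bimodal across probes (island probes low,
    # shore/body probes high), unimodal within probe across samples
    probe_mean = np.where(
        rng.random(npr) < 0.5, rng.beta(2, 8, npr), rng.beta(8, 2, npr)
    )
    probe_mean = np.clip(probe_mean, 0.03, 0.97)
    planted = [i for i, _ in config.planted_effects]
    if planted:
        # planted sites are variably methylated (mid-range means), like the
        # hits an EWAS can actually discover
        probe_mean[planted] = rng.uniform(0.25, 0.75, len(planted))
    # within-probe variation on the logit scale keeps beta in (0,1) without
    # boundary atoms; the scale targets a beta-scale SD of beta_within_sd at
    # mid-range means and shrinks towards the boundaries like real arrays
    logit_sd = np.minimum(config.beta_within_sd / (probe_mean * (1 - probe_mean)), 1.0)
    z = logit(probe_mean)[:, None] + rng.normal(0.0, 1.0, (npr, n_samples)) * logit_sd[:, None]
    beta = expit(z)
    for i in mm_idx:
        # two well-separated components within the probe
        comp = rng.random(n_samples) < 0.5
        centers = np.where(comp, logit(0.25), logit(0.75))
        beta[i] = expit(centers + rng.normal(0.0, 0.25, n_samples))
    return beta


def _beta_to_intensities(config, rng, beta, sample_shift):
    npr, n = beta.shape
    total = config.base_intensity * np.exp(
        rng.normal(0.0, config.intensity_log_sd, npr)
    )
    # brightness varies per observation (DNA amount, hybridization) but is
    # shared by the two channels, so it cancels in the beta-value; only the
    # channel-specific noise blurs methylation estimates
    common = sample_shift[None, :] + rng.normal(0.0, config.common_log_sd, (npr, n))
    log_m = (
        np.log(total[:, None] * beta)
        + common
        + rng.normal(0.0, config.noise_log_sd, (npr, n))
    )
    log_u = (
        np.log(total[:, None] * (1.0 - beta))
        + common
        + rng.normal(0.0, config.noise_log_sd, (npr, n))
    )
    return np.exp(log_m), np.exp(log_u)


def _simulate_controls(config, rng, n_samples, sample_shift):
    k = config.n_control_probes
    base = config.base_intensity * np.exp(rng.normal(0.0, 0.5, k))
    logc = (
        np.log(base)[:, None]
        + sample_shift[None, :]
        + rng.normal(0.0, config.noise_log_sd, (k, n_samples))
    )
    return pd.DataFrame(
        np.exp(logc),
        index=[f"ctrl{j:02d}" for j in range(k)],
        columns=[f"s{j:05d}" for j in range(n_samples)],
    )


def truth_report(ds: SyntheticDataset) -> pd.DataFrame:
    """One row per planted association effect: (probe_id, coefficient)."""
    return ds.truth_effects.copy()


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Emit the dataset in the TSV formats the pipeline reads, plus a truth
    sidecar (probe_id, coefficient)."""
    out = sio.ensure_dir(outdir)
    sio.write_intensities(
        ds.intensities, out / "methylated.tsv", out / "unmethylated.tsv"
    )
    sio.write_controls(ds.controls, out / "controls.tsv")
    sio.write_manifest(ds.manifest, out / "manifest.tsv")
    sio.write_cohort(ds.cohort, out / "cohort.tsv")
    ds.truth_effects.to_csv(out / "truth_effects.tsv", sep="\t", index=False)


def mean_sibship_size(cohort: pd.DataFrame) -> float:
    """Average number of members per sibship, rounded to two decimals."""
    return round(float(cohort.groupby("sibship_id").size().mean()), 2)
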