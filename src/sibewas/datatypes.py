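"""Core in-memory containers shared across the pipeline.

Tabular data (manifest, cohort, association results) travel as pandas
DataFrames with documented column contracts; the small fixed-shape bundles
below are dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns required of a probe manifest table.
MANIFEST_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "strand",
    "gene",
    "crossreactive_flag",
    "snp_overlap_flag",
]

#: Columns required of a cohort phenotype table.
COHORT_COLUMNS = [
    "sample_id",
    "sibship_id",
    "age",
    "sex",
    "bmi",
    "current_smoker",
    "hypertension",
    "crp",
]

#: Chromosome labels accepted in manifests.
VALID_CHROMOSOMES = frozenset([str(c) for c in range(1, 23)] + ["X", "Y"])

#: Model tags an association table may carry.
MODEL_TAGS = frozenset(
    ["primary", "pc_adjusted", "sensitivity_htn", "interaction", "subset1", "subset2"]
)


class FormatError(ValueError):
    """A file or table violates its format contract."""


@dataclass
class IntensityPair:
    """Methylated and unmethylated signal matrices, probes x samples."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame

    def __post_init__(self) -> None:
        m, u = self.methylated, self.unmethylated
        if not m.index.equals(u.index) or not m.columns.equals(u.columns):
            raise FormatError("methylated/unmethylated matrices are not aligned")
        if (m.values < 0).any() or (u.values < 0).any():
            raise FormatError("intensities must be non-negative")

    @property
    def probe_ids(self) -> pd.Index:
        return self.methylated.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.methylated.columns

    def select_samples(self, sample_ids) -> "IntensityPair":
        return IntensityPair(
            self.methylated.loc[:, sample_ids], self.unmethylated.loc[:, sample_ids]
        )

    def select_probes(self, probe_ids) -> "IntensityPair":
        return IntensityPair(
            self.methylated.loc[probe_ids], self.unmethylated.loc[probe_ids]
        )


@dataclass
class ControlPCA:
    """Orthogonalized control-probe predictors.

    ``component_scores`` holds per-sample scores (samples x k); scores of
    distinct components are orthogonal.  ``loadings`` maps the 56 control
    features onto components.
    """

    component_scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray
    k: int


@dataclass
class BetaMatrix:
    """Methylation beta-values (probes x samples) in [0, 1]."""

    values: pd.DataFrame
    offset_alpha: float = 100.0

    def __post_init__(self) -> None:
        v = self.values.values
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise ValueError("beta-values must lie in [0, 1]")


@dataclass
class QCReport:
    """Outcome of sample and site quality control."""

    excluded_samples: pd.DataFrame  # columns: sample_id, reason
    flagged_sites: pd.DataFrame  # columns: probe_id, reason
    n_sites_tested: int

    SITE_REASONS = frozenset(
        ["multimodal", "crossreactive", "snp_overlap", "sex_chromosome"]
    )


@dataclass
class SplitAssignment:
    """Two disjoint, individually unrelated sample subsets for replication."""

    subset1: list
    subset2: list
    seed: int
    dropped_singletons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.subset1) & set(self.subset2):
            raise ValueError("replication subsets overlap")
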