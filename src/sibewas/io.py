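"""Readers and writers for the pipeline's tab-delimited formats.

Every table is plain TSV with a header row.  Intensity matrices carry probes
as rows (first column ``probe_id``) and samples as columns.  All writers are
lossless for their readers.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .datatypes import (
    COHORT_COLUMNS,
    MANIFEST_COLUMNS,
    VALID_CHROMOSOMES,
    FormatError,
    IntensityPair,
)

log = logging.getLogger(__name__)


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "probe_id":
        raise FormatError(f"{path}: first column must be 'probe_id'")
    df = df.set_index("probe_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe_id {dup!r}")
    df.index.name = None
    return df.astype(float)


def read_intensities(path_m, path_u) -> IntensityPair:
    """Read aligned methylated/unmethylated intensity matrices.

    The two files must contain identical probe and sample sets; sample
    columns may appear in any order and are aligned to the methylated file.
    """
    m = _read_matrix(path_m)
    u = _read_matrix(path_u)
    if set(m.index) != set(u.index) or set(m.columns) != set(u.columns):
        only_m = (set(m.index) - set(u.index)) | (set(m.columns) - set(u.columns))
        only_u = (set(u.index) - set(m.index)) | (set(u.columns) - set(m.columns))
        raise FormatError(
            f"intensity files disagree: only in M={sorted(only_m)[:5]}, "
            f"only in U={sorted(only_u)[:5]}"
        )
    u = u.loc[m.index, m.columns]
    return IntensityPair(m, u)


def write_intensities(pair: IntensityPair, path_m, path_u) -> None:
    pair.methylated.to_csv(path_m, sep="\t", index_label="probe_id")
    pair.unmethylated.to_csv(path_u, sep="\t", index_label="probe_id")


def read_controls(path) -> pd.DataFrame:
    """Control-probe matrix: control features as rows, samples as columns."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "control_id":
        raise FormatError(f"{path}: first column must be 'control_id'")
    df = df.set_index("control_id").astype(float)
    df.index.name = None
    return df


def write_controls(controls: pd.DataFrame, path) -> None:
    controls.to_csv(path, sep="\t", index_label="control_id")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_manifest(path) -> pd.DataFrame:
    """Probe manifest with genomic annotation and exclusion flags."""
    df = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str, "chromosome": str, "gene": str}
    )
    _require_columns(df, MANIFEST_COLUMNS, path)
    df = df[MANIFEST_COLUMNS].copy()
    df["gene"] = df["gene"].fillna("")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"{path}: duplicate probe_id {dup!r}")
    bad_chrom = set(df["chromosome"]) - VALID_CHROMOSOMES
    if bad_chrom:
        raise FormatError(f"{path}: invalid chromosome label(s) {sorted(bad_chrom)}")
    if (df["position"] <= 0).any():
        raise FormatError(f"{path}: positions must be positive (1-based)")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand must be '+' or '-'")
    for c in ("crossreactive_flag", "snp_overlap_flag"):
        df[c] = df[c].astype(bool)
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_cohort(path, drop_incomplete: bool = True) -> pd.DataFrame:
    """Cohort phenotype table; samples with missing modeled covariates are
    dropped with a logged count."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sibship_id": str})
    _require_columns(df, COHORT_COLUMNS, path)
    df = df[COHORT_COLUMNS].copy()
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    if not df["sex"].isin(["M", "F"]).all():
        raise FormatError(f"{path}: sex must be 'M' or 'F'")
    incomplete = df[["age", "sex", "bmi", "current_smoker", "crp"]].isna().any(axis=1)
    if incomplete.any():
        if not drop_incomplete:
            raise FormatError(f"{path}: {int(incomplete.sum())} incomplete samples")
        log.info("dropping %d samples with incomplete phenotypes", incomplete.sum())
        df = df[~incomplete].reset_index(drop=True)
    if (df["crp"] <= 0).any():
        bad = df.loc[df["crp"] <= 0, "sample_id"].iloc[0]
        raise FormatError(f"{path}: non-positive CRP for sample {bad!r}")
    for c in ("current_smoker", "hypertension"):
        df[c] = df[c].astype(bool)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_association(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "model_tag": str})
    _require_columns(
        df, ["probe_id", "coefficient", "se", "p_value", "n_used", "model_tag"], path
    )
    return df


def write_association(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Term annotations as two-column TSV: term_id <TAB> gene.

    An optional third column supplies the term name.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least term_id and gene columns")
    df = df.iloc[:, :3] if df.shape[1] >= 3 else df
    df.columns = ["term_id", "gene"] + (["term_name"] if df.shape[1] == 3 else [])
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df


def read_gmt(path) -> pd.DataFrame:
    """GMT gene-set format: term, description, then one gene per field."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, name = parts[0], parts[1]
            for gene in parts[2:]:
                if gene:
                    rows.append((term, gene, name or term))
    if not rows:
        raise FormatError(f"{path}: no gene sets found")
    return pd.DataFrame(rows, columns=["term_id", "gene", "term_name"])


def load_config(path) -> dict:
    """YAML configuration for the simulator and analysis options."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
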