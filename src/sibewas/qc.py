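"""Sample- and site-level quality control.

Samples are excluded when any control-probe feature deviates more than
``k_sd`` standard deviations from that feature's cross-sample mean (default
4 SD).  Sites are flagged for multimodality (Hartigan dip test on either
intensity channel), for cross-reactive probes, for SNP-overlapping probes,
and for residing on the sex chromosomes.  Multimodal and sex-chromosome
sites are removed from association testing; cross-reactive and
SNP-overlapping sites are kept in the scan but reported separately so
results at those probes can be interpreted with caution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import IntensityPair, QCReport
from .dip import InsufficientDataError, dip_statistic, dip_test_pvalue

log = logging.getLogger(__name__)


def flag_samples_by_controls(controls: pd.DataFrame, k_sd: float = 4.0) -> list:
    """Samples whose control probes lie beyond ``k_sd`` SD of the feature mean.

    Zero-variance control features cannot flag anyone.  Means and SDs are
    computed across all samples, so the result is invariant to sample order.
    """
    if k_sd <= 0:
        raise ValueError(f"k_sd must be positive, got {k_sd}")
    if controls.shape[1] < 3:
        raise InsufficientDataError(
            f"sample QC needs at least 3 samples, got {controls.shape[1]}"
        )
    vals = controls.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(vals - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    bad = (z > k_sd).any(axis=0)
    excluded = [s for s, b in zip(controls.columns, bad) if b]
    log.info("sample QC: excluded %d of %d samples", len(excluded), controls.shape[1])
    return excluded


def flag_multimodal_sites(
    intensities: IntensityPair,
    alpha: float = 0.001,
    n_boot: int = 2000,
    seed: int = 0,
) -> list:
    """Probes whose dip-test p-value is below ``alpha`` on the methylated OR
    the unmethylated cross-sample intensities."""
    n = intensities.methylated.shape[1]
    flagged = []
    m_vals = intensities.methylated.to_numpy(dtype=float)
    u_vals = intensities.unmethylated.to_numpy(dtype=float)
    for i, probe in enumerate(intensities.probe_ids):
        for channel in (m_vals[i], u_vals[i]):
            d = dip_statistic(channel)
            if dip_test_pvalue(d, n, n_boot=n_boot, seed=seed) < alpha:
                flagged.append(probe)
                break
    log.info("dip test: flagged %d of %d probes", len(flagged), len(m_vals))
    return flagged


def apply_site_filters(
    manifest: pd.DataFrame,
    multimodal: list,
    drop_flagged: bool = False,
) -> tuple[list, QCReport]:
    """Site filtering: keep autosomal, non-multimodal probes.

    Cross-reactive and SNP-overlap probes are flagged in the report (one row
    per reason) but, unless ``drop_flagged`` is set, remain among the kept
    probes: they are tested and then reported separately downstream.
    """
    mm = set(multimodal)
    rows = []
    sexchrom = manifest["chromosome"].isin(["X", "Y"])
    for pid in manifest.loc[sexchrom, "probe_id"]:
        rows.append((pid, "sex_chromosome"))
    for pid in manifest.loc[manifest["probe_id"].isin(mm), "probe_id"]:
        rows.append((pid, "multimodal"))
    for pid in manifest.loc[manifest["crossreactive_flag"], "probe_id"]:
        rows.append((pid, "crossreactive"))
    for pid in manifest.loc[manifest["snp_overlap_flag"], "probe_id"]:
        rows.append((pid, "snp_overlap"))
    flagged_sites = pd.DataFrame(rows, columns=["probe_id", "reason"])

    drop = sexchrom | manifest["probe_id"].isin(mm)
    if drop_flagged:
        drop |= manifest["crossreactive_flag"] | manifest["snp_overlap_flag"]
    kept = manifest.loc[~drop, "probe_id"].tolist()
    report = QCReport(
        excluded_samples=pd.DataFrame(columns=["sample_id", "reason"]),
        flagged_sites=flagged_sites,
        n_sites_tested=len(kept),
    )
    return kept, report


def run_sample_qc(
    intensities: IntensityPair, controls: pd.DataFrame, k_sd: float = 4.0
) -> tuple[IntensityPair, pd.DataFrame, pd.DataFrame]:
    """Apply control-probe sample exclusion to intensities and controls.

    Returns the filtered pair and controls plus the exclusion table.
    """
    excluded = flag_samples_by_controls(controls, k_sd=k_sd)
    keep = [s for s in intensities.sample_ids if s not in set(excluded)]
    table = pd.DataFrame(
        {"sample_id": excluded, "reason": ["control_outlier"] * len(excluded)}
    )
    return intensities.select_samples(keep), controls.loc[:, keep], table
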