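"""Gene-set over-representation for genes harbouring significant sites.

Significant probes map to gene symbols through the manifest; each annotation
term is then tested with a one-sided hypergeometric upper tail against a
background that defaults to all genes on the tested array.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .correction import bh_qvalues

log = logging.getLogger(__name__)


def map_sites_to_genes(probe_ids, manifest: pd.DataFrame) -> set:
    """Unique non-empty gene symbols annotated to the given probes."""
    sub = manifest.set_index("probe_id").loc[list(probe_ids), "gene"]
    empty = int((sub == "").sum() + sub.isna().sum())
    if empty:
        log.info("%d probes without a gene annotation dropped", empty)
    return set(g for g in sub if isinstance(g, str) and g)


def hypergeometric_enrichment(
    query: set,
    background: set,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Upper-tail hypergeometric p per term.

    ``annotations`` has columns term_id, gene and optionally term_name.
    Terms are intersected with the background; for overlap k, term size K,
    query size q and background size N the p-value is P(X >= k) with
    X ~ Hypergeom(N, K, q).  Rows are sorted by p; BH q-values across terms
    are appended alongside the raw p-values.
    """
    query = set(query)
    background = set(background)
    if not query or not background:
        raise ValueError("query and background gene sets must be non-empty")
    if not query <= background:
        raise ValueError(
            f"query genes missing from background: {sorted(query - background)[:5]}"
        )
    n_bg = len(background)
    n_query = len(query)
    names = (
        annotations.drop_duplicates("term_id").set_index("term_id")["term_name"]
        if "term_name" in annotations.columns
        else None
    )
    rows = []
    for term_id, genes in annotations.groupby("term_id")["gene"]:
        term_genes = set(genes) & background
        if not term_genes:
            continue
        overlap = len(term_genes & query)
        # P(X >= overlap): sf(k-1)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(term_genes), n_query))
        rows.append(
            (
                term_id,
                names.get(term_id, term_id) if names is not None else term_id,
                len(term_genes),
                overlap,
                min(p, 1.0),
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "term_size", "overlap", "p_value", "q_value"]
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "term_size", "overlap", "p_value"]
    )
    out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
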