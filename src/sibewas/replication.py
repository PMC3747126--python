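"""Internal replication by splitting sibships into two unrelated subsets.

From every sibship with at least two members, one randomly chosen sibling
goes to subset 1 and a second, distinct sibling to subset 2; members beyond
the second stay unused.  Singletons are divided evenly at random (an odd
one out is dropped so the subsets stay the same size).  Within each subset
no two samples share a sibship, so top hits can be re-tested by ordinary
least squares in two independent groups with matched backgrounds.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import ModelSpec, build_covariate_matrix, ln_transform_crp
from .datatypes import SplitAssignment

log = logging.getLogger(__name__)


def split_sibships(cohort: pd.DataFrame, seed: int = 0) -> SplitAssignment:
    """Draw the two unrelated replication subsets; deterministic per seed."""
    if cohort["sibship_id"].nunique() < 2:
        raise ValueError("need at least 2 sibships to split")
    rng = np.random.default_rng(seed)
    subset1, subset2 = [], []
    singles = []
    for sib_id, members in cohort.groupby("sibship_id", sort=True)["sample_id"]:
        ids = members.tolist()
        if len(ids) == 1:
            singles.append(ids[0])
        else:
            pick = rng.choice(len(ids), size=2, replace=False)
            subset1.append(ids[pick[0]])
            subset2.append(ids[pick[1]])
    rng.shuffle(singles)
    dropped = []
    if len(singles) % 2:
        dropped = [singles.pop()]
        log.info("odd singleton count: dropping %s to keep subsets equal", dropped[0])
    half = len(singles) // 2
    subset1.extend(singles[:half])
    subset2.extend(singles[half:])
    return SplitAssignment(
        subset1=sorted(subset1), subset2=sorted(subset2), seed=seed,
        dropped_singletons=dropped,
    )


def _ols_scan(beta_df, cohort, spec, tag):
    y = ln_transform_crp(cohort.set_index("sample_id")["crp"])
    cov = build_covariate_matrix(cohort, spec).to_numpy()
    rows = []
    vals = beta_df.loc[:, cohort["sample_id"]].to_numpy(dtype=float)
    for i, pid in enumerate(beta_df.index):
        x = vals[i]
        design = np.column_stack([np.ones(x.size), x, cov])
        fit = sm.OLS(np.asarray(y), design).fit()
        rows.append(
            (pid, float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]),
             x.size, tag)
        )
    return pd.DataFrame(
        rows, columns=["probe_id", "coefficient", "se", "p_value", "n_used", "model_tag"]
    )


def replicate_top_hits(
    beta,
    cohort: pd.DataFrame,
    split: SplitAssignment,
    hits,
    alpha: float = 0.05,
    spec: ModelSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-test top hits in each unrelated subset by linear regression.

    The per-test threshold is ``alpha / len(hits)``.  Returns the two
    per-subset association tables (stacked) and a verdict table with one row
    per hit: p in each subset, verdict in {both, one, neither}, and whether
    the coefficient signs agree.
    """
    spec = spec or ModelSpec()
    bdf = beta.values if hasattr(beta, "offset_alpha") else beta
    hits = list(hits)
    missing = [h for h in hits if h not in bdf.index]
    if missing:
        raise KeyError(f"hit probe(s) missing from beta matrix: {missing[:5]}")
    sub = bdf.loc[hits]
    threshold = alpha / len(hits)

    coh = cohort.set_index("sample_id", drop=False)
    tables = []
    for tag, ids in (("subset1", split.subset1), ("subset2", split.subset2)):
        tables.append(_ols_scan(sub, coh.loc[ids], spec, tag))
    stacked = pd.concat(tables, ignore_index=True)

    t1 = tables[0].set_index("probe_id")
    t2 = tables[1].set_index("probe_id")
    verdicts = []
    for pid in hits:
        p1, p2 = float(t1.loc[pid, "p_value"]), float(t2.loc[pid, "p_value"])
        n_sig = int(p1 < threshold) + int(p2 < threshold)
        verdict = {2: "both", 1: "one", 0: "neither"}[n_sig]
        sign_ok = np.sign(t1.loc[pid, "coefficient"]) == np.sign(
            t2.loc[pid, "coefficient"]
        )
        verdicts.append((pid, p1, p2, verdict, bool(sign_ok)))
    verdict_table = pd.DataFrame(
        verdicts, columns=["probe_id", "p_subset1", "p_subset2", "verdict",
                           "sign_concordant"]
    )
    return stacked, verdict_table
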