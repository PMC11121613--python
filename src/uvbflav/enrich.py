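"""Pathway over-representation analysis against a local annotation table.

For each pathway with K annotated members in a background of N
features, a selected set of size n containing k pathway members is
scored by the upper-tail hypergeometric probability P(X >= k);
Benjamini-Hochberg adjustment runs across pathways.  Only
over-representation is tested.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["feature_id", "pathway_id", "pathway_name"]


def _check_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    missing = set(ANNOTATION_COLUMNS[:2]) - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if "pathway_name" not in annotation.columns:
        annotation = annotation.assign(pathway_name=annotation["pathway_id"])
    return annotation


def hypergeom_enrich(
    selected: Iterable[str],
    annotation: pd.DataFrame,
    background: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``selected`` per pathway.

    Requires ``selected`` to be a subset of ``background`` and every
    annotated member to be in the background.  Returns one row per
    pathway (pathway_id, pathway_name, k, n, K, N, p_value,
    adjusted_p), sorted by p-value.
    """
    selected = set(selected)
    background = set(background)
    if not background:
        raise ValueError("empty background")
    annotation = _check_annotation(annotation)
    if annotation.empty:
        raise ValueError("no annotation: the pathway table is empty")
    if not selected <= background:
        raise ValueError("selected set is not a subset of the background")
    outside = set(annotation["feature_id"]) - background
    if outside:
        raise ValueError(
            f"{len(outside)} annotated feature(s) missing from the background"
        )
    N, n = len(background), len(selected)
    rows = []
    for (pid, name), members in annotation.groupby(["pathway_id", "pathway_name"])["feature_id"]:
        mem = set(members)
        K = len(mem)
        k = len(mem & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {"pathway_id": pid, "pathway_name": name, "k": k, "n": n,
             "K": K, "N": N, "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values(["p_value", "pathway_id"], ignore_index=True)


def map_to_pathways(
    ids_by_role: Mapping[str, Iterable[str]],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-pathway membership counts of hit sets by role (e.g. DF / DEG).

    Ids absent from the annotation are counted as unmapped and logged.
    Returns (pathway_id, pathway_name, role, count, members).
    """
    annotation = _check_annotation(annotation)
    rows = []
    for role, ids in ids_by_role.items():
        ids = set(ids)
        annotated = annotation[annotation["feature_id"].isin(ids)]
        unmapped = ids - set(annotation["feature_id"])
        if unmapped:
            logger.info("%d %s id(s) not annotated to any pathway", len(unmapped), role)
        for (pid, name), members in annotated.groupby(["pathway_id", "pathway_name"])["feature_id"]:
            rows.append(
                {
                    "pathway_id": pid,
                    "pathway_name": name,
                    "role": role,
                    "count": len(set(members)),
                    "members": ";".join(sorted(set(members))),
                }
            )
    return pd.DataFrame(rows, columns=["pathway_id", "pathway_name", "role", "count", "members"])
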