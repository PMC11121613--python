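"""Differential-feature screening.

Two screens share one hit schema:

* Differential flavonoids / metabolites (DFs): selected when the OPLS
  VIP strictly exceeds 1 AND the linear fold change of group means is
  >= 1.5 (up) or <= 0.67 (down).  Fold change is treatment-mean over
  control-mean on the raw intensity scale.
* Differentially expressed genes (DEGs): per-gene Welch t-test on
  log2(FPKM + 1) with Benjamini-Hochberg adjustment; selected when
  q < 0.05 and the fold-change rule holds.  The default rule is
  |log2FC| >= 1; ``fc_rule="literal"`` keeps any gene with FC > 1.

Direction is up iff FC > 1; log2FC is log2 of the linear FC.  Venn
intersections and per-class up/down tallies summarise the hit sets.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

HIT_COLUMNS = ["feature_id", "comparison", "fc", "log2fc", "direction", "evidence", "class"]

DF_VIP_THRESHOLD = 1.0
DF_FC_UP = 1.5
DF_FC_DOWN = 0.67
DEG_Q_THRESHOLD = 0.05


def _group_mean(matrix: pd.DataFrame, groups: pd.Series, group: str) -> pd.Series:
    samples = groups.index[groups == group]
    missing = set(samples) - set(matrix.columns)
    if missing:
        raise ValueError(f"samples missing from matrix: {sorted(missing)}")
    if len(samples) == 0:
        raise ValueError(f"group {group!r} has no samples")
    return matrix[list(samples)].mean(axis=1)


def fold_changes(
    matrix: pd.DataFrame, groups: pd.Series, contrast: tuple[str, str]
) -> pd.DataFrame:
    """Linear FC (treatment/control of group means) and log2FC per feature."""
    control, treatment = contrast
    mean_c = _group_mean(matrix, groups, control)
    mean_t = _group_mean(matrix, groups, treatment)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_t / mean_c
        log2fc = np.log2(fc)
    return pd.DataFrame(
        {"mean_control": mean_c, "mean_treatment": mean_t, "fc": fc, "log2fc": log2fc}
    )


def _attach_class(hits: pd.DataFrame, classes: pd.DataFrame | None) -> pd.DataFrame:
    if classes is None or classes.empty:
        hits["class"] = "other"
        return hits
    lookup = classes.set_index(classes.columns[0])[classes.columns[1]]
    hits["class"] = hits["feature_id"].map(lookup).fillna("other")
    return hits


def df_stats(
    matrix: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str],
    vip: pd.Series,
) -> pd.DataFrame:
    """Per-feature VIP + fold-change table for the DF screen."""
    fcs = fold_changes(matrix, groups, contrast)
    stats_df = fcs.copy()
    stats_df["vip"] = vip.reindex(fcs.index)
    bad = ~np.isfinite(stats_df["fc"])
    if bad.any():
        logger.warning("excluding %d feature(s) with undefined fold change", int(bad.sum()))
    return stats_df


def screen_dfs(
    matrix: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str],
    vip: pd.Series,
    vip_threshold: float = DF_VIP_THRESHOLD,
    fc_up: float = DF_FC_UP,
    fc_down: float = DF_FC_DOWN,
    classes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Differential metabolites: VIP > 1 and (FC >= 1.5 or FC <= 0.67).

    The VIP inequality is strict; the fold-change bounds are inclusive,
    exactly as conventionally printed.  ``vip`` should come from a
    discriminant model already accepted by the Q² > 0.5 validity rule
    for the same contrast.
    """
    control, treatment = contrast
    stats_df = df_stats(matrix, groups, contrast, vip)
    ok = np.isfinite(stats_df["fc"]) & stats_df["vip"].notna()
    sel = ok & (stats_df["vip"] > vip_threshold) & (
        (stats_df["fc"] >= fc_up) | (stats_df["fc"] <= fc_down)
    )
    hits = stats_df.loc[sel].reset_index(names="feature_id")
    hits["comparison"] = f"{control}vs{treatment}"
    hits["direction"] = np.where(hits["fc"] > 1, "up", "down")
    hits["evidence"] = hits["vip"]
    hits = _attach_class(hits, classes)
    return hits[HIT_COLUMNS].sort_values("feature_id", ignore_index=True)


def _welch_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch t on the rows of two sample blocks.

    Degenerate rows (zero variance in both groups) get p = 1 when the
    means agree and p = 0 when they differ — the natural limit of the
    statistic as noise vanishes.
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p[degenerate & (m1 == m2)] = 1.0
    p[degenerate & (m1 != m2)] = 0.0
    return p


def deg_stats(
    fpkm: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Per-gene fold change, Welch p and BH q for one contrast.

    The test runs on log2(FPKM + 1); fold change is the ratio of the
    linear group mean FPKM.  Genes expressed in neither group (all-zero
    rows) are skipped with a warning.
    """
    control, treatment = contrast
    s_c = list(groups.index[groups == control])
    s_t = list(groups.index[groups == treatment])
    if not s_c or not s_t:
        raise ValueError("both contrast groups need samples")
    if (fpkm < 0).any().any():
        raise ValueError("FPKM values must be nonnegative")
    sub = fpkm[s_c + s_t]
    allzero = (sub == 0).all(axis=1)
    if allzero.any():
        logger.warning("skipping %d gene(s) with all-zero expression", int(allzero.sum()))
        sub = sub.loc[~allzero]
    fcs = fold_changes(sub, groups, contrast)
    logx = np.log2(sub + 1.0)
    p = _welch_pvalues(logx[s_c].to_numpy(), logx[s_t].to_numpy())
    q = multipletests(p, method="fdr_bh")[1]
    out = fcs.copy()
    out["p_value"] = p
    out["q_value"] = q
    return out


def screen_degs(
    fpkm: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str],
    q_threshold: float = DEG_Q_THRESHOLD,
    fc_rule: str = "log2",
    log2fc_threshold: float = 1.0,
    classes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Differentially expressed genes for one contrast.

    ``fc_rule="log2"`` (default) requires |log2FC| >= ``log2fc_threshold``
    with direction by sign; ``fc_rule="literal"`` requires FC > 1 (any
    up-regulation), the looser published wording.
    """
    control, treatment = contrast
    stats_df = deg_stats(fpkm, groups, contrast)
    finite = np.isfinite(stats_df["fc"])
    if fc_rule == "log2":
        fc_ok = finite & (stats_df["log2fc"].abs() >= log2fc_threshold)
    elif fc_rule == "literal":
        fc_ok = finite & (stats_df["fc"] > 1)
    else:
        raise ValueError("fc_rule must be 'log2' or 'literal'")
    sel = fc_ok & (stats_df["q_value"] < q_threshold)
    hits = stats_df.loc[sel].reset_index(names="feature_id")
    hits["comparison"] = f"{control}vs{treatment}"
    hits["direction"] = np.where(hits["fc"] > 1, "up", "down")
    hits["evidence"] = hits["q_value"]
    hits = _attach_class(hits, classes)
    return hits[HIT_COLUMNS].sort_values("feature_id", ignore_index=True)


def venn(set_a: Iterable[str], set_b: Iterable[str]) -> dict:
    """Two-set intersection bookkeeping with memberships."""
    a, b = set(set_a), set(set_b)
    return {
        "shared": sorted(a & b),
        "only_a": sorted(a - b),
        "only_b": sorted(b - a),
        "n_shared": len(a & b),
        "n_only_a": len(a - b),
        "n_only_b": len(b - a),
    }


def tally_by_class(hits: pd.DataFrame, classes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-class up/down contingency counts of a hit table.

    Unannotated features count under ``other``.  Row totals always add
    up to the hit count.
    """
    if hits.empty:
        return pd.DataFrame(columns=["class", "up", "down", "total"])
    work = hits.copy()
    if classes is not None:
        work = _attach_class(work.drop(columns=["class"], errors="ignore"), classes)
    table = (
        work.pivot_table(index="class", columns="direction", values="feature_id",
                         aggfunc="count", fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
        .reset_index()
    )
    table.columns.name = None
    table["total"] = table["up"] + table["down"]
    return table
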