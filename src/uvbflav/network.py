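"""Signed Pearson-correlation networks between omics layers.

All cross-layer feature pairs (e.g. differential flavonoids against
differential genes, or transcription-factor genes against flavonoid-
pathway enzyme genes) are tested on a shared ordered sample set
(typically all nine samples of the three-group design).  An edge is
kept when r² >= 0.8 (|r| >= 0.894) and the exact two-sided p-value of
the t transform t = r sqrt((n-2)/(1-r²)) with n-2 degrees of freedom
is below 0.05; edges carry the sign of r.  No multiple-testing
correction is applied across edges.
"""

from __future__ import annotations

import logging
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

R2_THRESHOLD = 0.8
P_THRESHOLD = 0.05

EDGE_COLUMNS = ["node_a", "role_a", "node_b", "role_b", "r", "r2", "p", "sign"]


def _standardize(matrix: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    """Row-standardize (mean 0, sd 1, ddof=1); drop constant rows."""
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("skipping %d constant profile(s)", int((~keep).sum()))
    X = X[keep]
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return Z, matrix.index[keep]


def pearson_matrix(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame) -> pd.DataFrame:
    """All cross-pair Pearson correlations (rows of A x rows of B)."""
    if list(matrix_a.columns) != list(matrix_b.columns):
        raise ValueError("matrices must share the same ordered samples")
    n = matrix_a.shape[1]
    if n < 3:
        raise ValueError("need at least 3 shared samples")
    Za, idx_a = _standardize(matrix_a)
    Zb, idx_b = _standardize(matrix_b)
    R = Za @ Zb.T / (n - 1)
    return pd.DataFrame(np.clip(R, -1.0, 1.0), index=idx_a, columns=idx_b)


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Exact two-sided p of Pearson r via the t transform, df = n - 2."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def correlation_network(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    threshold_r2: float = R2_THRESHOLD,
    threshold_p: float = P_THRESHOLD,
    role_a: str = "DF",
    role_b: str = "DEG",
) -> pd.DataFrame:
    """Thresholded signed edge list between two feature matrices.

    Edges are unordered: endpoints are canonically sorted by id, so
    swapping the two input layers yields the identical edge list (with
    roles following their nodes).  Constant profiles are skipped with a
    warning; self-pairings (identical ids across layers) are ignored.
    """
    R = pearson_matrix(matrix_a, matrix_b)
    n = matrix_a.shape[1]
    P = correlation_pvalues(R.to_numpy(), n)
    rows = []
    for i, ida in enumerate(R.index):
        for j, idb in enumerate(R.columns):
            if ida == idb:
                continue
            r = float(R.iat[i, j])
            r2 = r * r
            p = float(P[i, j])
            if r2 >= threshold_r2 and p < threshold_p:
                a, ra, b, rb = ida, role_a, idb, role_b
                if str(b) < str(a):
                    a, ra, b, rb = b, rb, a, ra
                rows.append(
                    {
                        "node_a": a, "role_a": ra, "node_b": b, "role_b": rb,
                        "r": r, "r2": r2, "p": p,
                        "sign": "positive" if r > 0 else "negative",
                    }
                )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return edges.sort_values(["node_a", "node_b"], ignore_index=True)


def node_summary(edges: pd.DataFrame) -> pd.DataFrame:
    """Per-node degree split into positive and negative edges."""
    rows: dict[str, dict] = {}
    for rec in edges.itertuples():
        for node, role in ((rec.node_a, rec.role_a), (rec.node_b, rec.role_b)):
            entry = rows.setdefault(node, {"node": node, "role": role, "positive": 0, "negative": 0})
            entry[rec.sign] += 1
    out = pd.DataFrame(rows.values(), columns=["node", "role", "positive", "negative"])
    if out.empty:
        return pd.DataFrame(columns=["node", "role", "positive", "negative", "degree"])
    out["degree"] = out["positive"] + out["negative"]
    return out.sort_values("node", ignore_index=True)


def tf_enzyme_chords(
    tf_expression: pd.DataFrame,
    enzyme_expression: pd.DataFrame,
    tf_families: Mapping[str, str],
    enzyme_symbols: Mapping[str, str] | None = None,
    threshold_r2: float = R2_THRESHOLD,
    threshold_p: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Correlation chords between TF genes and flavonoid-pathway enzyme genes.

    Individual TF genes carry their family label as role; enzyme genes
    carry their enzyme symbol (e.g. C12RT1, PGT1, FLS, DFR) when
    provided.
    """
    edges = correlation_network(
        tf_expression, enzyme_expression,
        threshold_r2=threshold_r2, threshold_p=threshold_p,
        role_a="TF", role_b="enzyme",
    )
    fam = dict(tf_families)
    sym = dict(enzyme_symbols or {})

    def relabel(node: str, role: str) -> str:
        if role == "TF":
            return fam.get(node, "TF")
        return sym.get(node, "enzyme")

    for side in ("a", "b"):
        edges[f"role_{side}"] = [
            relabel(n, r) for n, r in zip(edges[f"node_{side}"], edges[f"role_{side}"])
        ]
    return edges


def to_graph(edges: pd.DataFrame) -> nx.Graph:
    """Edge list as an undirected graph (GraphML-exportable)."""
    g = nx.Graph()
    for rec in edges.itertuples():
        g.add_node(rec.node_a, role=rec.role_a)
        g.add_node(rec.node_b, role=rec.role_b)
        g.add_edge(rec.node_a, rec.node_b, r=rec.r, r2=rec.r2, p=rec.p, sign=rec.sign)
    return g


def write_graphml(edges: pd.DataFrame, path) -> None:
    nx.write_graphml(to_graph(edges), path)
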