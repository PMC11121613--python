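"""PAM chlorophyll fluorescence parameters and group statistics.

Computes the two PSII quantum-efficiency ratios used throughout
stress physiology,

    Fv/Fm = (Fm - Fo) / Fm      (maximum efficiency, dark-adapted)
    Y(II) = (Fm' - F) / Fm'     (actual efficiency in light)

and summarises them per treatment group with mean +/- sd and a
compact-letter display from one-way ANOVA followed by a pairwise
post-hoc test (Tukey HSD by default, Fisher LSD optionally) at
alpha = 0.05: groups that share no letter differ significantly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

PARAMETERS = ("Fv/Fm", "Y(II)", "Fo")


@dataclass(frozen=True)
class PamRecord:
    """One PAM measurement: dark-adapted Fo/Fm and light-adapted Fm'/F."""

    sample_id: str
    group: str
    Fo: float
    Fm: float
    Fm_prime: float
    F: float

    def __post_init__(self) -> None:
        if self.Fm <= 0:
            raise ValueError("Fm must be positive")
        if not (self.Fm >= self.Fo >= 0):
            raise ValueError("require Fm >= Fo >= 0")
        if not (self.Fm_prime >= self.F >= 0):
            raise ValueError("require Fm_prime >= F >= 0")


def compute_fvfm(record: PamRecord) -> float:
    """Maximum PSII quantum efficiency, (Fm - Fo)/Fm."""
    if record.Fm == 0:
        raise ZeroDivisionError("Fm is zero")
    return (record.Fm - record.Fo) / record.Fm


def compute_yii(record: PamRecord) -> float:
    """Actual PSII quantum efficiency in light, (Fm' - F)/Fm'."""
    if record.Fm_prime == 0:
        raise ZeroDivisionError("Fm_prime is zero")
    return (record.Fm_prime - record.F) / record.Fm_prime


def records_from_frame(frame: pd.DataFrame) -> list[PamRecord]:
    required = {"sample_id", "group", "Fo", "Fm", "Fm_prime", "F"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"PAM table missing columns: {sorted(missing)}")
    return [
        PamRecord(
            sample_id=str(r.sample_id),
            group=str(r.group),
            Fo=float(r.Fo),
            Fm=float(r.Fm),
            Fm_prime=float(r.Fm_prime),
            F=float(r.F),
        )
        for r in frame.itertuples()
    ]


def parameter_values(records: Iterable[PamRecord], parameter: str) -> pd.DataFrame:
    """Long table (sample_id, group, value) for one parameter."""
    if parameter not in PARAMETERS:
        raise KeyError(f"unknown parameter {parameter!r}; choose from {PARAMETERS}")
    rows = []
    for r in records:
        if parameter == "Fv/Fm":
            v = compute_fvfm(r)
        elif parameter == "Y(II)":
            v = compute_yii(r)
        else:
            v = r.Fo
        rows.append({"sample_id": r.sample_id, "group": r.group, "value": v})
    return pd.DataFrame(rows)


def _pairwise_pvalues(
    samples: list[np.ndarray], method: str
) -> np.ndarray:
    """Symmetric matrix of pairwise post-hoc p-values."""
    k = len(samples)
    p = np.ones((k, k))
    if method == "tukey":
        res = stats.tukey_hsd(*samples)
        p = np.asarray(res.pvalue)
    elif method == "lsd":
        # Fisher LSD: pairwise t with the pooled within-group MSE.
        n_total = sum(len(s) for s in samples)
        df_err = n_total - k
        mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df_err
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(mse * (1 / len(samples[i]) + 1 / len(samples[j])))
                if se == 0:
                    pij = 1.0 if samples[i].mean() == samples[j].mean() else 0.0
                else:
                    t = (samples[i].mean() - samples[j].mean()) / se
                    pij = 2 * stats.t.sf(abs(t), df_err)
                p[i, j] = p[j, i] = pij
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    return p


def compact_letter_display(
    labels: Sequence[str], pvalues: np.ndarray, alpha: float = 0.05
) -> dict[str, str]:
    """Assign letters so groups share a letter iff not significantly different.

    Letters follow the maximal cliques of the non-significance graph,
    ordered by first group appearance, so the first group always gets
    an 'a'.  Groups in no clique of size > 1 receive their own letter.
    """
    k = len(labels)
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if pvalues[i, j] >= alpha:
                g.add_edge(i, j)
    cliques = [sorted(c) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (c[0], c))
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    for idx, clique in enumerate(cliques):
        letter = chr(ord("a") + idx)
        for member in clique:
            letters[labels[member]].append(letter)
    return {lab: "".join(sorted(ls)) for lab, ls in letters.items()}


def summarize_groups(
    records: Iterable[PamRecord] | pd.DataFrame,
    parameter: str,
    alpha: float = 0.05,
    method: str = "tukey",
) -> pd.DataFrame:
    """Group mean +/- sd with significance letters for one parameter.

    One-way ANOVA across groups, then a pairwise post-hoc test at
    ``alpha`` drives the compact-letter display.  Requires >= 2 groups
    with >= 2 replicates each.
    """
    if isinstance(records, pd.DataFrame):
        records = records_from_frame(records)
    values = parameter_values(records, parameter)
    groups = list(dict.fromkeys(values["group"]))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [values.loc[values["group"] == g, "value"].to_numpy() for g in groups]
    for g, s in zip(groups, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        # all observations identical: ANOVA undefined, nothing differs
        letters = {g: "a" for g in groups}
        anova_p = 1.0
    else:
        anova_p = float(stats.f_oneway(*samples).pvalue)
        pmat = _pairwise_pvalues(samples, method)
        letters = compact_letter_display(groups, pmat, alpha)
    out = pd.DataFrame(
        {
            "group": groups,
            "parameter": parameter,
            "mean": [s.mean() for s in samples],
            "sd": [s.std(ddof=1) for s in samples],
            "n": [len(s) for s in samples],
            "letter": [letters[g] for g in groups],
        }
    )
    out.attrs["anova_p"] = anova_p
    return out


def summary_table(
    records: Iterable[PamRecord] | pd.DataFrame,
    parameters: Sequence[str] = PARAMETERS,
    alpha: float = 0.05,
    method: str = "tukey",
) -> pd.DataFrame:
    """Stacked summaries for several parameters (report layout)."""
    recs = records_from_frame(records) if isinstance(records, pd.DataFrame) else list(records)
    return pd.concat(
        [summarize_groups(recs, p, alpha=alpha, method=method) for p in parameters],
        ignore_index=True,
    )
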