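"""Synthetic-data generators with known ground truth.

Every input the analysis consumes — fast fluorescence transients,
pulse-amplitude-modulation (PAM) records, a widely-targeted metabolite
intensity matrix, an FPKM gene-expression matrix, and the annotation
tables (flavonoid subclass, transcription-factor family, pathway
membership) — can be generated here under a known planted truth, so
that every downstream stage is testable without external data.

The emulated study design is three treatment groups (PAR control M,
UV-B radiation N, UV-B + abscisic acid Q) with three biological
replicates each; the metabolome defaults to 2148 features of which 487
carry a flavonoid subclass label, dominated by flavones (41%) and
flavonols (29%).

Model choices
-------------
* OJIP transients: a sum of three saturating-exponential rises (the
  O-J, J-I and I-P phases) between basal fluorescence ``f_o`` and
  maximal fluorescence ``f_m``, plus an optional Gaussian-in-log-time
  "K-band" bump centred at 300 µs.  This is the minimal curve family
  that reproduces every landmark the JIP-test reads (O, K at 300 µs,
  J at 2 ms, P at the maximum).
* Intensities and FPKM: log-normal baselines with multiplicative
  log-normal replicate noise parameterised by a coefficient of
  variation; planted features have group means scaled by
  ``2**log2fc`` along the chain of consecutive contrasts.
* All generators are pure functions of (parameters, seed); per-sample
  noise comes from named child streams of one master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import StudyDesign, child_rng, comparison_label
from .trace import FluorTrace

# Time (s) of the K and J landmarks of the fast fluorescence rise.
T_K = 3e-4
T_J = 2e-3

#: Flavonoid subclass mix of the emulated metabolome (fractions of the
#: flavonoid features; flavones and flavonols dominate).
FLAVONOID_SUBCLASS_PROPORTIONS: dict[str, float] = {
    "flavones": 0.41,
    "flavonols": 0.29,
    "flavanones": 0.09,
    "chalcones": 0.05,
    "flavanols": 0.05,
    "flavanonols": 0.04,
    "isoflavones": 0.03,
    "anthocyanidins": 0.02,
    "other flavonoids": 0.02,
}

#: Default transcription-factor family sizes of the emulated
#: transcriptome (the five largest families plus a tail).
DEFAULT_TF_FAMILY_SIZES: dict[str, int] = {
    "MYB": 154,
    "AP2-EREBP": 93,
    "mTERF": 89,
    "bHLH": 82,
    "C3H": 75,
    "NAC": 40,
    "ARF": 35,
    "WRKY": 30,
    "C2H2": 25,
    "GRAS": 20,
}

#: Default pathway annotation layout: (name, n metabolite members,
#: n gene members) for the two flavonoid pathways the analysis maps to.
DEFAULT_PATHWAY_SPEC: dict[str, tuple[str, int, int]] = {
    "ko00941": ("Flavonoid biosynthesis", 25, 30),
    "ko00944": ("Flavone and flavonol biosynthesis", 15, 12),
}


# ---------------------------------------------------------------------------
# OJIP transients
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OjipSimParams:
    """Parameters of the synthetic fast fluorescence rise.

    ``phase_weights`` split the total variable fluorescence
    ``f_m - f_o`` across the O-J, J-I and I-P phases;
    ``phase_timescales`` are the corresponding (strictly increasing)
    exponential time constants in seconds.  ``j_step_shift`` multiplies
    the O-J weight before renormalisation, raising (>1) or lowering
    (<1) the relative fluorescence at the J step; ``k_band_amp`` adds a
    Gaussian-in-log-time bump at 300 µs emulating donor-side
    (oxygen-evolving-complex) impairment.  ``noise_sd`` is the standard
    deviation of multiplicative log-normal noise.
    """

    f_o: float = 200.0
    f_m: float = 1200.0
    phase_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    phase_timescales: tuple[float, float, float] = (6e-4, 1e-2, 0.15)
    k_band_amp: float = 0.0
    j_step_shift: float = 1.0
    k_band_logwidth: float = 0.18
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.f_m > self.f_o > 0):
            raise ValueError("require f_m > f_o > 0")
        w = np.asarray(self.phase_weights, float)
        if w.size != 3 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("phase_weights must be 3 nonnegative fractions summing to 1")
        tau = np.asarray(self.phase_timescales, float)
        if tau.size != 3 or np.any(np.diff(tau) <= 0) or np.any(tau <= 0):
            raise ValueError("phase_timescales must be positive and strictly increasing")
        if self.j_step_shift <= 0:
            raise ValueError("j_step_shift must be positive")
        if self.noise_sd < 0 or self.k_band_amp < 0:
            raise ValueError("noise_sd and k_band_amp must be nonnegative")

    def effective_weights(self) -> np.ndarray:
        """Phase weights after the J-step shift, renormalised to 1."""
        w = np.asarray(self.phase_weights, float).copy()
        w[0] *= self.j_step_shift
        return w / w.sum()

    def ideal_curve(self, t: np.ndarray) -> np.ndarray:
        """Noise-free fluorescence at times ``t`` (closed form)."""
        t = np.asarray(t, float)
        w = self.effective_weights()
        tau = np.asarray(self.phase_timescales, float)
        rise = sum(w[i] * (1.0 - np.exp(-t / tau[i])) for i in range(3))
        f = self.f_o + (self.f_m - self.f_o) * rise
        if self.k_band_amp > 0:
            z = (np.log10(t) - np.log10(T_K)) / self.k_band_logwidth
            f = f + self.k_band_amp * np.exp(-0.5 * z * z)
        return f


def log_time_grid(n_points: int = 120, t_min: float = 1e-5, t_max: float = 1.0) -> np.ndarray:
    """Logarithmic sampling grid, 10 µs to 1 s by default."""
    return np.logspace(np.log10(t_min), np.log10(t_max), n_points)


def simulate_ojip(
    params: OjipSimParams | Mapping[str, OjipSimParams],
    design: StudyDesign,
    n_points: int = 120,
    t_min: float = 1e-5,
    t_max: float = 1.0,
) -> list[FluorTrace]:
    """Generate one transient per sample of the design.

    ``params`` is either a single parameter set applied to every group
    or a mapping group -> parameters (for treatment-specific J-step or
    K-band effects).  Deterministic given ``design.seed``.
    """
    if isinstance(params, OjipSimParams):
        per_group = {g: params for g in design.groups}
    else:
        per_group = dict(params)
        missing = set(design.groups) - set(per_group)
        if missing:
            raise ValueError(f"no OJIP parameters for groups {sorted(missing)}")
    t = log_time_grid(n_points, t_min, t_max)
    traces: list[FluorTrace] = []
    for group in design.groups:
        p = per_group[group]
        ideal = p.ideal_curve(t)
        for sid in design.samples_of(group):
            f = ideal.copy()
            if p.noise_sd > 0:
                rng = child_rng(design.seed, f"ojip:{sid}")
                f = f * np.exp(rng.normal(0.0, p.noise_sd, size=t.size))
            traces.append(FluorTrace(sample_id=sid, group=group, time_s=t, fluorescence=f))
    return traces


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------

_TRUTH_FILES = {
    "effects": ("effects.tsv", ["feature_id", "comparison", "log2fc"]),
    "classes": ("classes.tsv", ["feature_id", "class"]),
    "tf_families": ("tf_families.tsv", ["gene_id", "tf_family"]),
    "pathways": ("pathways.tsv", ["feature_id", "pathway_id", "pathway_name"]),
}


def _empty(cols: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


@dataclass
class PlantedTruth:
    """Ground truth of a simulation run.

    ``effects`` holds one row per planted (feature, comparison) with the
    true log2 fold change (treatment over control); ``classes`` the
    flavonoid subclass per metabolite; ``tf_families`` and ``pathways``
    the annotation truth.  Round-trips losslessly through TSV.
    """

    effects: pd.DataFrame = field(default_factory=lambda: _empty(_TRUTH_FILES["effects"][1]))
    classes: pd.DataFrame = field(default_factory=lambda: _empty(_TRUTH_FILES["classes"][1]))
    tf_families: pd.DataFrame = field(default_factory=lambda: _empty(_TRUTH_FILES["tf_families"][1]))
    pathways: pd.DataFrame = field(default_factory=lambda: _empty(_TRUTH_FILES["pathways"][1]))

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for attr, (fname, _) in _TRUTH_FILES.items():
            getattr(self, attr).to_csv(outdir / fname, sep="\t", index=False)

    @classmethod
    def read(cls, outdir) -> "PlantedTruth":
        outdir = Path(outdir)
        kwargs = {}
        for attr, (fname, cols) in _TRUTH_FILES.items():
            path = outdir / fname
            if path.exists():
                df = pd.read_csv(path, sep="\t")
                if df.empty:
                    df = _empty(cols)
                kwargs[attr] = df
        return cls(**kwargs)

    def equals(self, other: "PlantedTruth") -> bool:
        for attr in _TRUTH_FILES:
            a, b = getattr(self, attr), getattr(other, attr)
            if len(a) != len(b):
                return False
            if len(a) and not a.reset_index(drop=True).equals(b.reset_index(drop=True)):
                return False
        return True

    def effects_for(self, comparison: str) -> pd.Series:
        sub = self.effects[self.effects["comparison"] == comparison]
        return sub.set_index("feature_id")["log2fc"].astype(float)


def random_planted_effects(
    feature_ids: Sequence[str],
    comparison: str,
    n_up: int,
    n_down: int,
    magnitude: float,
    rng: np.random.Generator,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Draw disjoint up/down feature sets with |log2fc| = ``magnitude``."""
    pool = [f for f in feature_ids if f not in set(exclude)]
    if n_up + n_down > len(pool):
        raise ValueError("not enough features to plant the requested effects")
    chosen = rng.choice(np.asarray(pool, dtype=object), size=n_up + n_down, replace=False)
    lfc = np.concatenate([np.full(n_up, magnitude), np.full(n_down, -magnitude)])
    return pd.DataFrame(
        {"feature_id": chosen, "comparison": comparison, "log2fc": lfc}
    )


# ---------------------------------------------------------------------------
# Omics matrices
# ---------------------------------------------------------------------------


def _allocate_counts(total: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``total`` across classes."""
    props = dict(proportions)
    s = sum(props.values())
    if s > 1.0 + 1e-9 or any(v < 0 for v in props.values()):
        raise ValueError("class proportions must be nonnegative and sum to <= 1")
    raw = {k: total * v / s for k, v in props.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(props, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _group_means(
    design: StudyDesign,
    base: pd.Series,
    effects: pd.DataFrame,
) -> pd.DataFrame:
    """Per-group true means: baseline scaled along the contrast chain."""
    means = pd.DataFrame({design.groups[0]: base})
    for control, treatment in design.comparisons():
        label = comparison_label(control, treatment)
        lfc = pd.Series(0.0, index=base.index)
        if len(effects):
            sub = effects[effects["comparison"] == label]
            bad = set(sub["feature_id"]) - set(base.index)
            if bad:
                raise ValueError(f"planted features absent from matrix: {sorted(bad)[:5]}")
            lfc.loc[sub["feature_id"].to_numpy()] = sub["log2fc"].to_numpy(dtype=float)
        means[treatment] = means[control] * np.power(2.0, lfc)
    return means


def _noisy_matrix(
    design: StudyDesign,
    means: pd.DataFrame,
    cv: float,
    stream: str,
) -> pd.DataFrame:
    cols = {}
    sigma = float(np.sqrt(np.log1p(cv * cv))) if cv > 0 else 0.0
    for group in design.groups:
        mu = means[group].to_numpy()
        for sid in design.samples_of(group):
            if sigma > 0:
                rng = child_rng(design.seed, f"{stream}:{sid}")
                # mean-preserving multiplicative log-normal noise
                noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=mu.size))
                cols[sid] = mu * noise
            else:
                cols[sid] = mu.copy()
    return pd.DataFrame(cols, index=means.index)


def simulate_metabolome(
    design: StudyDesign,
    n_features: int = 2148,
    n_flavonoids: int = 487,
    class_proportions: Mapping[str, float] | None = None,
    planted_effects: pd.DataFrame | None = None,
    cv: float = 0.1,
    base_log10_mean: float = 6.0,
    base_log10_sd: float = 0.6,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Widely-targeted metabolome emulation (features x samples).

    Baseline intensities are log-normal around 10**6 instrument counts;
    the first ``n_flavonoids`` features carry a flavonoid subclass label
    allocated by ``class_proportions`` (defaults to a flavone/flavonol-
    dominated mix).  ``planted_effects`` is a table with columns
    ``feature_id`` (or positional index), ``comparison``, ``log2fc``.
    Returns the intensity matrix and the planted truth.
    """
    if n_flavonoids > n_features:
        raise ValueError("n_flavonoids cannot exceed n_features")
    props = dict(class_proportions or FLAVONOID_SUBCLASS_PROPORTIONS)
    counts = _allocate_counts(n_flavonoids, props)

    width = max(5, len(str(n_features)))
    ids = [f"MET{i:0{width}d}" for i in range(1, n_features + 1)]
    labels: list[str] = []
    for subclass, k in counts.items():
        labels.extend([subclass] * k)
    classes = pd.DataFrame(
        {"feature_id": ids[: n_flavonoids], "class": labels[:n_flavonoids]}
    )

    rng = child_rng(design.seed, "metabolome:base")
    base = pd.Series(
        np.power(10.0, rng.normal(base_log10_mean, base_log10_sd, size=n_features)),
        index=ids,
    )
    effects = (
        planted_effects.copy()
        if planted_effects is not None
        else _empty(_TRUTH_FILES["effects"][1])
    )
    means = _group_means(design, base, effects)
    matrix = _noisy_matrix(design, means, cv, "metabolome")
    truth = PlantedTruth(effects=effects, classes=classes)
    return matrix, truth


def simulate_transcriptome(
    design: StudyDesign,
    n_genes: int = 5000,
    planted_effects: pd.DataFrame | None = None,
    cv: float = 0.1,
    base_log10_mean: float = 1.0,
    base_log10_sd: float = 0.5,
    fixed_group_means: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """FPKM gene-expression emulation on a log-normal baseline.

    ``fixed_group_means`` (genes x groups) pins the true per-group means
    of selected genes exactly — useful for reproducing worked examples
    where printed FPKM values are the input.
    """
    width = max(5, len(str(n_genes)))
    ids = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    rng = child_rng(design.seed, "transcriptome:base")
    base = pd.Series(
        np.power(10.0, rng.normal(base_log10_mean, base_log10_sd, size=n_genes)),
        index=ids,
    )
    effects = (
        planted_effects.copy()
        if planted_effects is not None
        else _empty(_TRUTH_FILES["effects"][1])
    )
    means = _group_means(design, base, effects)
    if fixed_group_means is not None:
        missing = set(fixed_group_means.columns) - set(design.groups)
        if missing:
            raise ValueError(f"fixed_group_means has unknown groups {sorted(missing)}")
        for gid, row in fixed_group_means.iterrows():
            if gid not in means.index:
                means.loc[gid] = float(row.iloc[0])
            for g, v in row.items():
                means.loc[gid, g] = float(v)
    matrix = _noisy_matrix(design, means, cv, "transcriptome")
    truth = PlantedTruth(effects=effects)
    return matrix, truth


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def simulate_annotations(
    gene_ids: Sequence[str],
    metabolite_ids: Sequence[str] = (),
    tf_family_sizes: Mapping[str, int] | None = None,
    pathway_spec: Mapping[str, tuple[str, int, int]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transcription-factor-family and pathway annotation tables.

    Returns ``(tf_table, pathway_table)``: ``tf_table`` maps each
    regulator gene to exactly one family (default family sizes put MYB
    first with 154 members); ``pathway_table`` assigns metabolites and
    genes to KEGG-style pathway ids (by default the flavonoid
    biosynthesis pathway ko00941 and the flavone/flavonol pathway
    ko00944).  Every annotated id is drawn from the supplied universe.
    """
    sizes = dict(tf_family_sizes or DEFAULT_TF_FAMILY_SIZES)
    if any(v < 0 for v in sizes.values()):
        raise ValueError("family sizes must be nonnegative")
    total_tf = sum(sizes.values())
    if total_tf > len(gene_ids):
        raise ValueError("TF family sizes exceed the number of genes")
    rng = child_rng(seed, "annotations")
    chosen = rng.choice(np.asarray(gene_ids, dtype=object), size=total_tf, replace=False)
    fam_col: list[str] = []
    for fam, k in sizes.items():
        fam_col.extend([fam] * k)
    tf_table = pd.DataFrame({"gene_id": chosen, "tf_family": fam_col})
    if tf_table["gene_id"].duplicated().any():
        raise ValueError("duplicate gene -> family assignment")

    spec = dict(pathway_spec or DEFAULT_PATHWAY_SPEC)
    rows = []
    for pid, (name, n_met, n_gene) in spec.items():
        if n_met > len(metabolite_ids) or n_gene > len(gene_ids):
            raise ValueError(f"pathway {pid} larger than the id universe")
        if n_met:
            mets = rng.choice(np.asarray(metabolite_ids, dtype=object), size=n_met, replace=False)
            rows.extend({"feature_id": m, "pathway_id": pid, "pathway_name": name} for m in mets)
        if n_gene:
            genes = rng.choice(np.asarray(gene_ids, dtype=object), size=n_gene, replace=False)
            rows.extend({"feature_id": g, "pathway_id": pid, "pathway_name": name} for g in genes)
    pathway_table = (
        pd.DataFrame(rows, columns=["feature_id", "pathway_id", "pathway_name"])
        if rows
        else _empty(_TRUTH_FILES["pathways"][1])
    )
    return tf_table, pathway_table


# ---------------------------------------------------------------------------
# PAM records
# ---------------------------------------------------------------------------

#: Per-group PAM targets (Fv/Fm, Y(II), Fo) of the emulated experiment:
#: UV-B depresses the quantum efficiencies, ABA partially restores them.
DEFAULT_PAM_TARGETS: dict[str, tuple[float, float, float]] = {
    "M": (0.80, 0.18, 0.1065),
    "N": (0.57, 0.13, 0.1072),
    "Q": (0.68, 0.17, 0.1056),
}


def simulate_pam(
    design: StudyDesign,
    targets: Mapping[str, tuple[float, float, float]] | None = None,
    noise_sd: float = 0.01,
) -> pd.DataFrame:
    """Per-sample PAM records around group targets.

    Targets are (Fv/Fm, Y(II), Fo) per group; Fm is derived as
    ``Fo / (1 - Fv/Fm)``, the light-adapted maximum Fm' as 60% of Fm
    and the steady-state F as ``Fm' * (1 - Y(II))``.  Multiplicative
    noise with relative sd ``noise_sd`` is applied per sample to each
    underlying quantity while preserving the record invariants.
    """
    tgt = dict(targets or DEFAULT_PAM_TARGETS)
    missing = set(design.groups) - set(tgt)
    if missing:
        raise ValueError(f"no PAM targets for groups {sorted(missing)}")
    rows = []
    for group in design.groups:
        fvfm, yii, fo = tgt[group]
        if not (0 <= fvfm < 1 and 0 <= yii < 1 and fo > 0):
            raise ValueError("PAM targets out of range")
        for sid in design.samples_of(group):
            rng = child_rng(design.seed, f"pam:{sid}")
            jitter = np.exp(rng.normal(0.0, noise_sd, size=3)) if noise_sd > 0 else np.ones(3)
            fo_s = fo * jitter[0]
            fvfm_s = min(fvfm * jitter[1], 0.999)
            yii_s = min(yii * jitter[2], 0.999)
            fm_s = fo_s / (1.0 - fvfm_s)
            fm_prime = 0.6 * fm_s
            f_s = fm_prime * (1.0 - yii_s)
            rows.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "Fo": fo_s,
                    "Fm": fm_s,
                    "Fm_prime": fm_prime,
                    "F": f_s,
                }
            )
    return pd.DataFrame(rows)
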