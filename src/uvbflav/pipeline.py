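"""End-to-end orchestration: simulate -> PAM/JIP-test -> OPLS-DA ->
screening -> enrichment -> correlation network, with a consolidated,
reproducible report.

The default configuration runs the whole chain on synthetic data with
planted group contrasts strong enough to yield valid discriminant
models for both contrasts; every stage writes plain TSV under
``out/<stage>/`` plus a consolidated ``report.tsv`` / ``report.md``
with a count ledger (up + down = total per comparison and layer) and a
provenance block (config hash, seed, package versions).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import StudyDesign, child_rng, comparison_label
from .trace import write_traces
from . import enrich as enrich_mod
from . import network as network_mod
from . import ojip as ojip_mod
from . import opls as opls_mod
from . import pam as pam_mod
from . import screen as screen_mod
from . import synth

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    vip: float = 1.0
    fc_up: float = 1.5
    fc_down: float = 0.67
    q: float = 0.05
    deg_log2fc: float = 1.0
    r2: float = 0.8
    p: float = 0.05
    q2_validity: float = 0.5

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class SimulationSettings:
    """Size and effect structure of the synthetic run.

    Planted effect counts echo the asymmetry of a UV-B experiment
    (many responders to radiation, fewer to the hormone), scaled to
    desk-size matrices; magnitudes of |log2FC| = 2 with 10% replicate
    CV give clearly separable classes.
    """

    n_features: int = 2148
    n_flavonoids: int = 487
    n_genes: int = 2000
    metabolite_cv: float = 0.1
    gene_cv: float = 0.1
    df_up: dict = field(default_factory=lambda: {"MvsN": 80, "NvsQ": 18})
    df_down: dict = field(default_factory=lambda: {"MvsN": 30, "NvsQ": 30})
    deg_up: dict = field(default_factory=lambda: {"MvsN": 120, "NvsQ": 18})
    deg_down: dict = field(default_factory=lambda: {"MvsN": 60, "NvsQ": 30})
    effect_log2fc: float = 2.0
    ojip_noise_sd: float = 0.02
    ojip_j_step_shift: dict = field(default_factory=lambda: {"M": 1.0, "N": 1.25, "Q": 1.1})
    ojip_k_band_amp: dict = field(default_factory=lambda: {"M": 0.0, "N": 60.0, "Q": 25.0})


@dataclass
class RunConfig:
    seed: int = 0
    groups: tuple = ("M", "N", "Q")
    replicates_per_group: int = 3
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    n_ortho: int = 1
    cv_folds: int = 7
    run_pam: bool = True
    run_ojip: bool = True
    run_network: bool = True
    outdir: str = "out"

    def design(self) -> StudyDesign:
        return StudyDesign(
            groups=tuple(self.groups),
            replicates_per_group=self.replicates_per_group,
            seed=self.seed,
        )

    def to_yaml(self, path=None) -> str:
        payload = asdict(self)
        payload["groups"] = list(self.groups)
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = yaml.safe_load(text)
        payload["groups"] = tuple(payload.get("groups", ("M", "N", "Q")))
        if "thresholds" in payload:
            payload["thresholds"] = Thresholds(**payload["thresholds"])
        if "simulation" in payload:
            payload["simulation"] = SimulationSettings(**payload["simulation"])
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    ledger: pd.DataFrame          # comparison, layer, up, down, total
    verdicts: pd.DataFrame        # contrast, q2, valid
    stage_tables: dict
    provenance: dict


def count_ledger(rows: list[tuple[str, str, int, int]]) -> pd.DataFrame:
    """Build a (comparison, layer, up, down, total) ledger table."""
    ledger = pd.DataFrame(rows, columns=["comparison", "layer", "up", "down"])
    ledger["total"] = ledger["up"] + ledger["down"]
    return ledger


def ledger_check(report: RunReport) -> tuple[bool, list[str]]:
    """Verify the report's internal arithmetic.

    Checks up + down = total on every ledger row, Venn counts bounded
    by their set sizes, and per-class tallies summing to the hit count.
    """
    violations: list[str] = []
    for rec in report.ledger.itertuples():
        if rec.up + rec.down != rec.total:
            violations.append(
                f"{rec.comparison}/{rec.layer}: {rec.up} + {rec.down} != {rec.total}"
            )
    for name, table in report.stage_tables.items():
        if name.startswith("venn_"):
            if table["n_shared"] > min(table["n_a"], table["n_b"]):
                violations.append(f"{name}: shared exceeds a set size")
        if name.startswith("tally_"):
            hits_key = name.replace("tally_", "hits_")
            if hits_key in report.stage_tables:
                if table["total"].sum() != len(report.stage_tables[hits_key]):
                    violations.append(f"{name}: tally total != hit count")
    return (not violations), violations


def _planted_effects(cfg: RunConfig, feature_ids, layer: str) -> pd.DataFrame:
    sim = cfg.simulation
    up = sim.df_up if layer == "metabolome" else sim.deg_up
    down = sim.df_down if layer == "metabolome" else sim.deg_down
    rng = child_rng(cfg.seed, f"plant:{layer}")
    frames, used = [], []
    for label in cfg.design().comparison_labels():
        eff = synth.random_planted_effects(
            feature_ids, label, up.get(label, 0), down.get(label, 0),
            sim.effect_log2fc, rng, exclude=used,
        )
        used.extend(eff["feature_id"])
        frames.append(eff)
    return pd.concat(frames, ignore_index=True)


def run_all(config: RunConfig) -> RunReport:
    """Execute every configured stage in dependency order.

    Deterministic given ``config.seed``; a failure in any stage raises
    with the stage name in the message.  Writes TSV outputs under
    ``config.outdir`` and returns the consolidated report.
    """
    cfg = config
    design = cfg.design()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    ledger_rows: list[tuple[str, str, int, int]] = []
    verdict_rows: list[dict] = []

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    def run_stage(name, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # re-raise labeled, halting the run
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    # --- simulate -----------------------------------------------------
    def _simulate():
        sim = cfg.simulation
        met_ids = [f"MET{i:0{max(5, len(str(sim.n_features)))}d}" for i in range(1, sim.n_features + 1)]
        gene_ids = [f"G{i:0{max(5, len(str(sim.n_genes)))}d}" for i in range(1, sim.n_genes + 1)]
        met_effects = _planted_effects(cfg, met_ids, "metabolome")
        gene_effects = _planted_effects(cfg, gene_ids, "transcriptome")
        metabolome, met_truth = synth.simulate_metabolome(
            design, n_features=sim.n_features, n_flavonoids=sim.n_flavonoids,
            planted_effects=met_effects, cv=sim.metabolite_cv,
        )
        transcriptome, gene_truth = synth.simulate_transcriptome(
            design, n_genes=sim.n_genes, planted_effects=gene_effects, cv=sim.gene_cv,
        )
        tf_sizes = dict(synth.DEFAULT_TF_FAMILY_SIZES)
        total_tf = sum(tf_sizes.values())
        if total_tf > sim.n_genes:  # shrink families proportionally for small runs
            scale = 0.5 * sim.n_genes / total_tf
            tf_sizes = {k: max(1, int(v * scale)) for k, v in tf_sizes.items()}
        tf_table, pathway_table = synth.simulate_annotations(
            gene_ids=list(transcriptome.index),
            metabolite_ids=list(metabolome.index),
            tf_family_sizes=tf_sizes,
            seed=cfg.seed,
        )
        ojip_params = {
            g: synth.OjipSimParams(
                j_step_shift=sim.ojip_j_step_shift.get(g, 1.0),
                k_band_amp=sim.ojip_k_band_amp.get(g, 0.0),
                noise_sd=sim.ojip_noise_sd,
            )
            for g in design.groups
        }
        traces = synth.simulate_ojip(ojip_params, design)
        pam_records = synth.simulate_pam(design)
        d = stage_dir("simulate")
        metabolome.rename_axis("feature_id").to_csv(d / "metabolome.tsv", sep="\t")
        transcriptome.rename_axis("feature_id").to_csv(d / "transcriptome.tsv", sep="\t")
        design.group_map().to_csv(d / "groups.tsv", sep="\t")
        tf_table.to_csv(d / "tf_families.tsv", sep="\t", index=False)
        pathway_table.to_csv(d / "pathways.tsv", sep="\t", index=False)
        write_traces(traces, d / "ojip_traces.tsv")
        pam_records.to_csv(d / "pam.tsv", sep="\t", index=False)
        met_truth.write(d / "truth_metabolome")
        gene_truth.write(d / "truth_transcriptome")
        return metabolome, transcriptome, met_truth, tf_table, pathway_table, traces, pam_records

    metabolome, transcriptome, met_truth, tf_table, pathway_table, traces, pam_records = run_stage(
        "simulate", _simulate
    )
    groups = design.group_map()

    # --- pam ----------------------------------------------------------
    if cfg.run_pam:
        def _pam():
            table = pam_mod.summary_table(pam_records)
            table.to_csv(stage_dir("pam") / "summary.tsv", sep="\t", index=False)
            return table

        tables["pam_summary"] = run_stage("pam", _pam)

    # --- ojip ---------------------------------------------------------
    if cfg.run_ojip:
        def _ojip():
            d = stage_dir("ojip")
            lm = ojip_mod.landmark_table(traces)
            lm.to_csv(d / "landmarks.tsv", sep="\t", index=False)
            by_group = {g: [t for t in traces if t.group == g] for g in design.groups}
            rows = []
            for control, treatment in design.comparisons():
                label = comparison_label(control, treatment)
                dv = ojip_mod.delta_curves(by_group[treatment], by_group[control], "Vt")
                dw = ojip_mod.delta_curves(by_group[treatment], by_group[control], "Wt")
                pd.DataFrame({"time_s": dv.time_s, "dVt": dv.values, "dWt": dw.values}).to_csv(
                    d / f"delta_{label}.tsv", sep="\t", index=False
                )
                rows.append({"comparison": label, "delta_J": dv.delta_j, "delta_K": dw.delta_k})
            summary = pd.DataFrame(rows)
            summary.to_csv(d / "delta_summary.tsv", sep="\t", index=False)
            return lm, summary

        tables["ojip_landmarks"], tables["ojip_delta"] = run_stage("ojip", _ojip)

    # --- opls + screening per contrast -------------------------------
    df_sets: dict[str, set] = {}
    deg_sets: dict[str, set] = {}
    for control, treatment in design.comparisons():
        label = comparison_label(control, treatment)

        def _contrast(control=control, treatment=treatment, label=label):
            sub_samples = design.samples_of(control) + design.samples_of(treatment)
            X = metabolome[sub_samples].T
            y = groups.loc[sub_samples].to_numpy()
            model = opls_mod.fit_opls(X, y, n_ortho=cfg.n_ortho)
            q2 = opls_mod.cross_validated_q2(
                X, y, n_ortho=cfg.n_ortho, folds=cfg.cv_folds, seed=cfg.seed
            )
            model.q2 = q2
            vip = opls_mod.compute_vip(model)
            valid = opls_mod.validate_model(q2, cfg.thresholds.q2_validity)
            d = stage_dir("opls")
            opls_mod.model_summary(model).to_csv(d / f"model_{label}.tsv", sep="\t", index=False)
            vip.rename_axis("feature_id").to_csv(d / f"vip_{label}.tsv", sep="\t")
            hits_df = screen_mod.screen_dfs(
                metabolome, groups, (control, treatment), vip,
                vip_threshold=cfg.thresholds.vip, fc_up=cfg.thresholds.fc_up,
                fc_down=cfg.thresholds.fc_down, classes=met_truth.classes,
            )
            hits_deg = screen_mod.screen_degs(
                transcriptome, groups, (control, treatment),
                q_threshold=cfg.thresholds.q, log2fc_threshold=cfg.thresholds.deg_log2fc,
            )
            ds = stage_dir("screen")
            hits_df.to_csv(ds / f"dfs_{label}.tsv", sep="\t", index=False)
            hits_deg.to_csv(ds / f"degs_{label}.tsv", sep="\t", index=False)
            tally = screen_mod.tally_by_class(hits_df)
            tally.to_csv(ds / f"tally_{label}.tsv", sep="\t", index=False)
            return q2, valid, hits_df, hits_deg, tally

        q2, valid, hits_df, hits_deg, tally = run_stage(f"contrast:{label}", _contrast)
        verdict_rows.append({"contrast": label, "q2": q2, "valid": valid})
        tables[f"hits_df_{label}"] = hits_df
        tables[f"hits_deg_{label}"] = hits_deg
        tables[f"tally_df_{label}"] = tally
        df_sets[label] = set(hits_df["feature_id"])
        deg_sets[label] = set(hits_deg["feature_id"])
        ledger_rows.append(
            (label, "DF", int((hits_df["direction"] == "up").sum()),
             int((hits_df["direction"] == "down").sum()))
        )
        ledger_rows.append(
            (label, "DEG", int((hits_deg["direction"] == "up").sum()),
             int((hits_deg["direction"] == "down").sum()))
        )

    # --- venn ---------------------------------------------------------
    labels = design.comparison_labels()
    if len(labels) >= 2:
        for layer, sets in (("df", df_sets), ("deg", deg_sets)):
            v = screen_mod.venn(sets[labels[0]], sets[labels[1]])
            tables[f"venn_{layer}"] = {
                "n_shared": v["n_shared"], "n_only_a": v["n_only_a"],
                "n_only_b": v["n_only_b"],
                "n_a": len(sets[labels[0]]), "n_b": len(sets[labels[1]]),
            }
            pd.DataFrame([tables[f"venn_{layer}"]]).to_csv(
                stage_dir("screen") / f"venn_{layer}.tsv", sep="\t", index=False
            )

    # --- enrichment ---------------------------------------------------
    def _enrich():
        d = stage_dir("enrich")
        results = {}
        met_annot = pathway_table[pathway_table["feature_id"].isin(metabolome.index)]
        for label in labels:
            if met_annot.empty:
                raise ValueError("no annotation available for enrichment")
            res = enrich_mod.hypergeom_enrich(
                df_sets[label], met_annot, list(metabolome.index)
            )
            res.to_csv(d / f"df_enrichment_{label}.tsv", sep="\t", index=False)
            results[f"enrich_df_{label}"] = res
        mapping = enrich_mod.map_to_pathways(
            {"DF": df_sets[labels[0]], "DEG": deg_sets[labels[0]]}, pathway_table
        )
        mapping.to_csv(d / "pathway_membership.tsv", sep="\t", index=False)
        results["pathway_membership"] = mapping
        return results

    tables.update(run_stage("enrich", _enrich))

    # --- network ------------------------------------------------------
    if cfg.run_network:
        def _network():
            d = stage_dir("network")
            df_ids = sorted(set().union(*df_sets.values()))
            deg_ids = sorted(set().union(*deg_sets.values()))
            edges = network_mod.correlation_network(
                metabolome.loc[df_ids], transcriptome.loc[deg_ids],
                threshold_r2=cfg.thresholds.r2, threshold_p=cfg.thresholds.p,
            )
            edges.to_csv(d / "df_deg_edges.tsv", sep="\t", index=False)
            network_mod.node_summary(edges).to_csv(d / "node_summary.tsv", sep="\t", index=False)
            tf_genes = tf_table[tf_table["gene_id"].isin(deg_ids)]
            enzyme_pool = pathway_table[
                pathway_table["feature_id"].isin(deg_ids)
                & pathway_table["feature_id"].isin(transcriptome.index)
            ]["feature_id"].unique()
            if len(tf_genes) and len(enzyme_pool):
                chords = network_mod.tf_enzyme_chords(
                    transcriptome.loc[tf_genes["gene_id"]],
                    transcriptome.loc[enzyme_pool],
                    tf_families=dict(zip(tf_table["gene_id"], tf_table["tf_family"])),
                    threshold_r2=cfg.thresholds.r2, threshold_p=cfg.thresholds.p,
                )
            else:
                chords = pd.DataFrame(columns=network_mod.EDGE_COLUMNS)
            chords.to_csv(d / "tf_enzyme_chords.tsv", sep="\t", index=False)
            return edges, chords

        tables["network_edges"], tables["tf_chords"] = run_stage("network", _network)

    ledger = count_ledger(ledger_rows)
    verdicts = pd.DataFrame(verdict_rows)
    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    report = RunReport(
        ledger=ledger, verdicts=verdicts, stage_tables=tables, provenance=provenance
    )
    write_report(report, out)
    return report


def write_report(report: RunReport, outdir) -> None:
    out = Path(outdir)
    report.ledger.to_csv(out / "report.tsv", sep="\t", index=False)
    lines = ["# Run report", "", "## Provenance", ""]
    lines += [f"- {k}: {v}" for k, v in report.provenance.items()]
    lines += ["", "## Model validity", ""]
    for rec in report.verdicts.itertuples():
        verdict = "valid" if rec.valid else "invalid"
        lines.append(f"- {rec.contrast}: Q2 = {rec.q2:.3f} ({verdict})")
    lines += ["", "## Count ledger", "", report.ledger.to_string(index=False)]
    ok, violations = ledger_check(report)
    lines += ["", f"Ledger check: {'pass' if ok else 'FAIL'}"]
    lines += [f"- {v}" for v in violations]
    (out / "report.md").write_text("\n".join(lines) + "\n")
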