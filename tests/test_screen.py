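"""Differential screening rules: VIP x FC for metabolites, q x FC for genes."""

import numpy as np
import pandas as pd
import pytest

from uvbflav.design import StudyDesign
from uvbflav.screen import (
    deg_stats,
    screen_degs,
    screen_dfs,
    tally_by_class,
    venn,
)
from uvbflav.synth import simulate_transcriptome


def matrix_from_group_means(means: dict[str, dict[str, float]], reps=3) -> tuple[pd.DataFrame, pd.Series]:
    """Noise-free matrix from feature -> group -> mean."""
    groups = list(next(iter(means.values())))
    cols, gm = {}, {}
    for g in groups:
        for i in range(1, reps + 1):
            sid = f"{g}{i}"
            cols[sid] = [means[f][g] for f in means]
            gm[sid] = g
    matrix = pd.DataFrame(cols, index=list(means))
    return matrix, pd.Series(gm, name="group").rename_axis("sample_id")


class TestDfScreen:
    @pytest.mark.parametrize(
        "vip,fc,selected,direction",
        [
            (1.2, 1.5, True, "up"),     # inclusive FC boundary
            (1.2, 0.67, True, "down"),  # inclusive lower boundary
            (0.9, 3.0, False, None),    # VIP filter dominates
            (1.0, 3.0, False, None),    # VIP threshold is strict
            (1.2, 1.49, False, None),
            (1.2, 0.68, False, None),
        ],
    )
    def test_threshold_boundaries(self, vip, fc, selected, direction):
        matrix, groups = matrix_from_group_means({"feat": {"M": 100.0, "N": 100.0 * fc}})
        vips = pd.Series({"feat": vip})
        hits = screen_dfs(matrix, groups, ("M", "N"), vips)
        assert (len(hits) == 1) is selected
        if selected:
            assert hits.loc[0, "direction"] == direction
            assert hits.loc[0, "fc"] == pytest.approx(fc)

    def test_log2fc_consistency_and_direction(self):
        means = {f"f{i}": {"M": 100.0, "N": 100.0 * fc}
                 for i, fc in enumerate([2.0, 0.5, 1.6, 0.6])}
        matrix, groups = matrix_from_group_means(means)
        vips = pd.Series(2.0, index=matrix.index)
        hits = screen_dfs(matrix, groups, ("M", "N"), vips)
        assert len(hits) == 4
        for rec in hits.itertuples():
            assert rec.log2fc == pytest.approx(np.log2(rec.fc), abs=1e-9)
            assert (rec.direction == "up") == (rec.fc > 1)

    def test_monotone_in_both_thresholds(self, rng):
        n = 200
        means = {
            f"f{i}": {"M": m, "N": m * fc}
            for i, (m, fc) in enumerate(
                zip(rng.uniform(50, 500, n), rng.lognormal(0, 0.8, n))
            )
        }
        matrix, groups = matrix_from_group_means(means)
        vips = pd.Series(rng.lognormal(0, 0.5, n), index=matrix.index)
        counts_vip = [
            len(screen_dfs(matrix, groups, ("M", "N"), vips, vip_threshold=v))
            for v in (0.5, 1.0, 1.5, 2.0)
        ]
        assert counts_vip == sorted(counts_vip, reverse=True)
        counts_fc = [
            len(screen_dfs(matrix, groups, ("M", "N"), vips,
                           fc_up=u, fc_down=1 / u))
            for u in (1.2, 1.5, 2.0, 3.0)
        ]
        assert counts_fc == sorted(counts_fc, reverse=True)

    def test_zero_denominator_feature_excluded(self, caplog):
        matrix, groups = matrix_from_group_means(
            {"ok": {"M": 10.0, "N": 40.0}, "zero": {"M": 0.0, "N": 40.0}}
        )
        vips = pd.Series(2.0, index=matrix.index)
        with caplog.at_level("WARNING"):
            hits = screen_dfs(matrix, groups, ("M", "N"), vips)
        assert hits["feature_id"].tolist() == ["ok"]


class TestDegScreen:
    # published worked examples: mean FPKM pairs and their log2 ratios
    TABLE_ROWS = [
        ("C12RT1", 13.35, 18.85, 0.50, "up"),
        ("DFR", 37.19, 66.67, 0.84, "up"),
        ("FLS_DN8661", 43.70, 38.56, -0.18, "down"),
    ]

    def test_published_fpkm_pairs_reproduce_printed_log2fc(self, design):
        fixed = pd.DataFrame(
            {"N": {g: n for g, n, q, *_ in self.TABLE_ROWS},
             "Q": {g: q for g, n, q, *_ in self.TABLE_ROWS}}
        )
        fpkm, _ = simulate_transcriptome(design, n_genes=20, cv=0.0,
                                         fixed_group_means=fixed)
        stats = deg_stats(fpkm, design.group_map(), ("N", "Q"))
        for gene, _, _, printed, direction in self.TABLE_ROWS:
            assert round(float(stats.loc[gene, "log2fc"]), 2) == printed
            assert (stats.loc[gene, "fc"] > 1) == (direction == "up")

    def test_identical_means_never_selected(self):
        matrix, groups = matrix_from_group_means(
            {f"g{i}": {"M": 50.0, "N": 50.0} for i in range(10)}
        )
        hits = screen_degs(matrix, groups, ("M", "N"))
        assert hits.empty

    def test_strong_difference_with_replicate_noise_selected(self):
        rng = np.random.default_rng(0)
        cols, gm = {}, {}
        base = rng.uniform(20, 80, 50)
        lift = np.ones(50)
        lift[:5] = 8.0  # five genes strongly up in N
        for g, mult in (("M", np.ones(50)), ("N", lift)):
            for i in range(1, 4):
                sid = f"{g}{i}"
                cols[sid] = base * mult * rng.lognormal(0, 0.05, 50)
                gm[sid] = g
        fpkm = pd.DataFrame(cols, index=[f"g{i}" for i in range(50)])
        groups = pd.Series(gm).rename_axis("sample_id")
        hits = screen_degs(fpkm, groups, ("M", "N"))
        assert set(hits["feature_id"]) == {f"g{i}" for i in range(5)}
        assert (hits["direction"] == "up").all()

    def test_literal_fc_rule(self):
        matrix, groups = matrix_from_group_means(
            {"g_up": {"M": 10.0, "N": 15.0}, "g_dn": {"M": 10.0, "N": 7.0}}
        )
        # zero variance, unequal means -> p = 0 -> q = 0 < 0.05
        hits = screen_degs(matrix, groups, ("M", "N"), fc_rule="literal")
        assert hits["feature_id"].tolist() == ["g_up"]

    def test_all_zero_gene_skipped(self, caplog):
        matrix, groups = matrix_from_group_means(
            {"dead": {"M": 0.0, "N": 0.0}, "live": {"M": 10.0, "N": 80.0}}
        )
        with caplog.at_level("WARNING"):
            stats = deg_stats(matrix, groups, ("M", "N"))
        assert "dead" not in stats.index


class TestVennAndTally:
    @pytest.mark.parametrize(
        "a,b,shared,only_a,only_b",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, 2, 1, 1),
            ({"a"}, {"b"}, 0, 1, 1),
            ({"a", "b"}, {"a", "b"}, 2, 0, 0),
        ],
    )
    def test_venn_counts(self, a, b, shared, only_a, only_b):
        v = venn(a, b)
        assert (v["n_shared"], v["n_only_a"], v["n_only_b"]) == (shared, only_a, only_b)
        assert set(v["shared"]) == a & b

    def test_tally_counts_by_class_and_direction(self):
        hits = pd.DataFrame(
            {
                "feature_id": [f"m{i}" for i in range(5)],
                "comparison": "MvsN",
                "fc": [2, 2, 2, 0.5, 0.5],
                "log2fc": [1, 1, 1, -1, -1],
                "direction": ["up", "up", "up", "down", "down"],
                "evidence": 2.0,
                "class": ["flavones"] * 3 + ["flavonols"] * 2,
            }
        )
        table = tally_by_class(hits).set_index("class")
        assert table.loc["flavones", "up"] == 3
        assert table.loc["flavones", "down"] == 0
        assert table.loc["flavonols", "down"] == 2
        assert table["total"].sum() == len(hits)

    def test_tally_empty_hits(self):
        assert tally_by_class(pd.DataFrame(columns=["feature_id", "direction", "class"])).empty

    def test_tally_matches_planted_classes_at_zero_noise(self):
        means = {}
        classes = []
        for i in range(6):
            fid = f"m{i}"
            up = i < 4
            means[fid] = {"M": 100.0, "N": 400.0 if up else 25.0}
            classes.append({"feature_id": fid,
                            "class": "flavones" if up else "flavonols"})
        matrix, groups = matrix_from_group_means(means)
        vips = pd.Series(2.0, index=matrix.index)
        hits = screen_dfs(matrix, groups, ("M", "N"), vips,
                          classes=pd.DataFrame(classes))
        table = tally_by_class(hits).set_index("class")
        assert table.loc["flavones", "up"] == 4
        assert table.loc["flavonols", "down"] == 2
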