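"""Generator contracts: determinism, planted truth, landmark fidelity."""

import numpy as np
import pandas as pd
import pytest

from uvbflav.design import StudyDesign
from uvbflav.ojip import delta_curves, extract_landmarks
from uvbflav.opls import compute_vip, fit_opls
from uvbflav.screen import deg_stats, screen_dfs
from uvbflav.synth import (
    DEFAULT_TF_FAMILY_SIZES,
    OjipSimParams,
    PlantedTruth,
    random_planted_effects,
    simulate_annotations,
    simulate_metabolome,
    simulate_ojip,
    simulate_pam,
    simulate_transcriptome,
)


class TestOjipGenerator:
    def test_same_seed_gives_bitwise_identical_traces(self, design):
        p = OjipSimParams(noise_sd=0.05)
        a = simulate_ojip(p, design)
        b = simulate_ojip(p, design)
        for ta, tb in zip(a, b):
            assert ta.sample_id == tb.sample_id
            np.testing.assert_array_equal(ta.fluorescence, tb.fluorescence)

    def test_identical_groups_give_zero_difference_curves(self, design):
        p = OjipSimParams(noise_sd=0.0, k_band_amp=0.0, j_step_shift=1.0)
        traces = simulate_ojip(p, design)
        m = [t for t in traces if t.group == "M"]
        n = [t for t in traces if t.group == "N"]
        for kind in ("Vt", "Wt"):
            d = delta_curves(n, m, kind)
            np.testing.assert_allclose(d.values, 0.0, atol=1e-12)

    def test_vj_matches_analytic_rise_at_2ms(self, design):
        # independent closed form: V(t) = sum_i w_i (1 - exp(-t/tau_i))
        w = (0.5, 0.3, 0.2)
        tau = (6e-4, 1e-2, 0.15)
        expected_vj = sum(wi * (1 - np.exp(-2e-3 / ti)) for wi, ti in zip(w, tau))
        p = OjipSimParams(phase_weights=w, phase_timescales=tau, noise_sd=0.0)
        trace = simulate_ojip(p, design)[0]
        lm = extract_landmarks(trace)
        assert lm.v_j == pytest.approx(expected_vj, abs=0.05)

    def test_traces_are_nonnegative_and_span_fo_to_fm(self, design):
        p = OjipSimParams(f_o=200, f_m=1200, noise_sd=0.0)
        for trace in simulate_ojip(p, design):
            assert np.all(trace.fluorescence >= 0)
            assert trace.fluorescence[0] == pytest.approx(200, rel=0.05)
            assert trace.fluorescence.max() == pytest.approx(1200, rel=0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"phase_weights": (0.5, 0.3, 0.3)},
            {"phase_weights": (-0.1, 0.6, 0.5)},
            {"phase_timescales": (1e-2, 1e-3, 0.1)},
            {"f_o": 500.0, "f_m": 400.0},
            {"j_step_shift": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OjipSimParams(**kwargs)


class TestMetabolomeGenerator:
    def test_flavonoid_label_count_matches_defaults(self, design):
        _, truth = simulate_metabolome(design, cv=0.0)
        assert len(truth.classes) == 487
        matrix, _ = simulate_metabolome(design, cv=0.0)
        assert matrix.shape == (2148, 9)
        assert (matrix > 0).all().all()

    def test_zero_noise_no_effects_gives_equal_group_means(self, design):
        matrix, _ = simulate_metabolome(design, n_features=50, n_flavonoids=10, cv=0.0)
        gm = design.group_map()
        means = {g: matrix[gm.index[gm == g]].mean(axis=1) for g in design.groups}
        pd.testing.assert_series_equal(means["M"], means["N"], check_names=False)
        pd.testing.assert_series_equal(means["N"], means["Q"], check_names=False)

    def test_planted_effect_scales_group_means(self, design):
        eff = pd.DataFrame(
            {"feature_id": ["MET00001"], "comparison": ["MvsN"], "log2fc": [2.0]}
        )
        matrix, _ = simulate_metabolome(
            design, n_features=30, n_flavonoids=5, planted_effects=eff, cv=0.0
        )
        gm = design.group_map()
        m = matrix.loc["MET00001", gm.index[gm == "M"]].mean()
        n = matrix.loc["MET00001", gm.index[gm == "N"]].mean()
        assert n / m == pytest.approx(4.0, rel=1e-12)

    def test_bad_class_proportions_rejected(self, design):
        with pytest.raises(ValueError):
            simulate_metabolome(design, class_proportions={"a": 0.9, "b": 0.4})

    def test_truth_round_trips_through_tsv(self, design, tmp_path):
        eff = random_planted_effects(
            [f"MET{i:05d}" for i in range(1, 31)], "MvsN", 3, 2, 1.5,
            np.random.default_rng(0),
        )
        _, truth = simulate_metabolome(
            design, n_features=30, n_flavonoids=8, planted_effects=eff, cv=0.0
        )
        truth.write(tmp_path / "truth")
        reloaded = PlantedTruth.read(tmp_path / "truth")
        assert truth.equals(reloaded)


class TestTranscriptomeGenerator:
    def test_fixed_group_means_reproduce_published_ratio(self, design):
        fixed = pd.DataFrame({"N": [13.35], "Q": [18.85]}, index=["C12RT1"])
        fpkm, _ = simulate_transcriptome(
            design, n_genes=10, cv=0.0, fixed_group_means=fixed
        )
        stats = deg_stats(fpkm, design.group_map(), ("N", "Q"))
        assert round(float(stats.loc["C12RT1", "log2fc"]), 2) == 0.50

    def test_same_seed_gives_identical_matrix(self, design):
        a, _ = simulate_transcriptome(design, n_genes=40, cv=0.2)
        b, _ = simulate_transcriptome(design, n_genes=40, cv=0.2)
        pd.testing.assert_frame_equal(a, b)

    def test_null_bh_false_discovery_controlled(self):
        """With no planted effects the BH screen rarely rejects anything."""
        any_discovery = 0
        n_seeds = 100
        for seed in range(n_seeds):
            design = StudyDesign(groups=("M", "N"), seed=seed)
            fpkm, _ = simulate_transcriptome(design, n_genes=300, cv=0.15)
            stats = deg_stats(fpkm, design.group_map(), ("M", "N"))
            any_discovery += int((stats["q_value"] < 0.05).any())
        # all hypotheses are null, so FDR = P(any rejection) <= 0.05
        assert any_discovery / n_seeds <= 0.10


class TestAnnotations:
    def test_default_family_sizes(self, design):
        genes = [f"G{i:05d}" for i in range(1, 1001)]
        tf, pathways = simulate_annotations(genes, [f"MET{i:05d}" for i in range(1, 101)])
        counts = tf["tf_family"].value_counts()
        assert counts["MYB"] == 154
        assert counts["AP2-EREBP"] == 93
        assert not tf["gene_id"].duplicated().any()
        assert set(tf["gene_id"]) <= set(genes)
        assert {"ko00941", "ko00944"} <= set(pathways["pathway_id"])

    def test_family_sizes_exceeding_genes_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotations([f"G{i}" for i in range(10)], [],
                                 tf_family_sizes={"MYB": 20})

    def test_total_family_assignments(self):
        genes = [f"G{i:05d}" for i in range(1, 2001)]
        mets = [f"MET{i:05d}" for i in range(1, 101)]
        tf, _ = simulate_annotations(genes, mets)
        assert len(tf) == sum(DEFAULT_TF_FAMILY_SIZES.values())


class TestPamGenerator:
    def test_records_satisfy_invariants(self, design):
        records = simulate_pam(design)
        assert len(records) == design.n_samples
        assert (records["Fm"] >= records["Fo"]).all()
        assert (records["Fm_prime"] >= records["F"]).all()
        assert (records["F"] >= 0).all()


class TestNullCalibration:
    def test_df_screen_size_bracketed_by_marginal_pass_rates(self):
        """Under the null the joint VIP+FC pass count sits between the
        product of the marginal pass rates (the filters are positively
        dependent, both reading the same group contrast) and the
        smaller marginal."""
        n_feat = 200
        joint = vip_pass = fc_pass = 0
        n_seeds = 50
        for seed in range(n_seeds):
            design = StudyDesign(groups=("M", "N"), seed=1000 + seed)
            matrix, _ = simulate_metabolome(
                design, n_features=n_feat, n_flavonoids=50, cv=0.3
            )
            gm = design.group_map()
            X = matrix.T
            model = fit_opls(X, gm.loc[X.index].to_numpy(), n_ortho=0)
            vip = compute_vip(model).reindex(matrix.index)
            hits = screen_dfs(matrix, gm, ("M", "N"), vip)
            means = {g: matrix[gm.index[gm == g]].mean(axis=1) for g in ("M", "N")}
            fc = means["N"] / means["M"]
            joint += len(hits)
            vip_pass += int((vip > 1).sum())
            fc_pass += int(((fc >= 1.5) | (fc <= 0.67)).sum())
        total = n_seeds * n_feat
        # expected joint count under independence, with Monte-Carlo slack
        lower = 0.8 * (vip_pass * fc_pass) / total
        upper = min(vip_pass, fc_pass)
        assert lower <= joint <= upper
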