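import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import latent_log2_cohort
from tck import simulate, stats
from tck.containers import ExpressionMatrix
from tck.stats import Thresholds


class TestMaxDeviation:
    def test_constant_profile_is_zero(self):
        prof = pd.Series([5.0, 5.0, 5.0], index=[0.0, 2.0, 4.0])
        assert stats.max_deviation(prof) == (0.0, 0.0)

    def test_hand_computed_profile(self):
        prof = pd.Series([5.0, 6.5, 5.2], index=[0.0, 2.0, 4.0])
        max_abs, signed = stats.max_deviation(prof)
        assert max_abs == pytest.approx(1.5)
        assert signed == pytest.approx(1.5)

    def test_signed_keeps_direction_of_largest_excursion(self):
        prof = pd.Series([5.0, 4.0, 7.5], index=[0.0, 2.0, 4.0])
        assert stats.max_deviation(prof)[1] == pytest.approx(2.5)
        prof = pd.Series([5.0, 2.0, 6.5], index=[0.0, 2.0, 4.0])
        assert stats.max_deviation(prof)[1] == pytest.approx(-3.0)

    def test_missing_interior_point_skipped(self):
        prof = pd.Series([5.0, 6.0, np.nan, 5.1], index=[0.0, 2.0, 4.0, 8.0])
        assert stats.max_deviation(prof)[0] == pytest.approx(1.0)

    def test_missing_baseline_errors(self):
        prof = pd.Series([6.0, 5.0], index=[2.0, 4.0])
        with pytest.raises(ValueError, match="baseline"):
            stats.max_deviation(prof)


class TestTimecourseGate:
    def test_low_noise_null_pass_rate_below_one_percent(self):
        cfg = simulate.SimulationConfig(n_features=1000, n_mirnas=0, noise_sd=0.1, seed=21)
        m, design = latent_log2_cohort(cfg, [], np.random.default_rng(21))
        gate = stats.timecourse_gate(m, design)
        assert gate["passes_tc_gate"].mean() <= 0.01

    def test_activation_ramp_always_passes(self):
        cfg = simulate.SimulationConfig(n_features=100, n_mirnas=0, noise_sd=0.1, seed=22)
        signals = simulate.activation_marker_signals(cfg, n_markers=20, plateau_log2=2.0)
        m, design = latent_log2_cohort(cfg, signals, np.random.default_rng(22))
        gate = stats.timecourse_gate(m, design)
        marker_ids = [s.feature_id for s in signals]
        assert gate.loc[marker_ids, "passes_tc_gate"].all()

    def test_fold_change_threshold_constructor(self):
        thr = Thresholds.from_fold_change(1.5)
        assert thr.tc_log2 == pytest.approx(np.log2(1.5))


def random_groups(rng, n_feat=20, n1=5, n2=5):
    return rng.normal(0, 1, (n_feat, n1)), rng.normal(0.3, 1.2, (n_feat, n2))


class TestShrinkageT:
    def test_lambda_zero_equals_welch_t(self):
        rng = np.random.default_rng(31)
        X1, X2 = random_groups(rng, n_feat=20, n1=5, n2=5)
        t, _, _, _ = stats.shrinkage_t(X1, X2, lambda_override=0.0)
        ref = sps.ttest_ind(X1, X2, axis=1, equal_var=False).statistic
        assert np.allclose(t, ref, atol=1e-12)

    def test_lambda_one_ranks_by_mean_difference(self):
        rng = np.random.default_rng(32)
        X1, X2 = random_groups(rng)
        t, _, st1, st2 = stats.shrinkage_t(X1, X2, lambda_override=1.0)
        diff = X1.mean(axis=1) - X2.mean(axis=1)
        assert np.array_equal(np.argsort(np.abs(t)), np.argsort(np.abs(diff)))
        assert np.allclose(st1.v_g_star, st1.v_target)

    def test_identical_variances_make_shrinkage_a_noop(self):
        base = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        X = np.vstack([base + c for c in range(6)])  # equal variance per row
        st = stats.shrink_variances(X)
        assert st.lambda_star == 1.0
        assert np.allclose(st.v_g_star, st.v_g)

    def test_lambda_star_always_in_unit_interval(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            X = rng.normal(0, rng.uniform(0.1, 3), (rng.integers(5, 50), 5))
            st = stats.shrink_variances(X)
            assert 0.0 <= st.lambda_star <= 1.0
            lo = np.minimum(st.v_g, st.v_target)
            hi = np.maximum(st.v_g, st.v_target)
            assert ((st.v_g_star >= lo - 1e-12) & (st.v_g_star <= hi + 1e-12)).all()

    def test_identical_groups_give_zero_t_and_p_one(self):
        X = np.tile(np.arange(5.0), (3, 1))
        t, p, _, _ = stats.shrinkage_t(X, X.copy())
        assert np.allclose(t, 0.0)
        assert np.allclose(p, 1.0)

    def test_sign_matches_mean_difference(self):
        rng = np.random.default_rng(34)
        X1, X2 = random_groups(rng)
        t, _, _, _ = stats.shrinkage_t(X1, X2)
        diff = X1.mean(axis=1) - X2.mean(axis=1)
        assert np.array_equal(np.sign(t), np.sign(diff))


def bh_oracle(p):
    """Brute-force BH step-up: find the largest j with p_(j) <= j*alpha/m,
    expressed as adjusted p-values via the cumulative-minimum rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestDifferentialTable:
    def test_median_fc_of_shifted_groups(self):
        # PD {1..5} vs HC {0..4}: medians 3 and 2, fc = 1
        cfg = simulate.SimulationConfig(n_features=1, n_mirnas=0, donors_per_group=5,
                                        time_points_h=(0.0, 2.0))
        rows = []
        vals = {}
        for g, pre, offs in (("PD", "P", 1.0), ("HC", "C", 0.0)):
            for d in range(5):
                for t in (0.0, 2.0):
                    sid = f"{pre}{d + 1}_{t:g}h"
                    rows.append((sid, f"{pre}{d + 1}", g, t, "B1"))
                    vals[sid] = d + offs
        from tck.containers import CohortDesign

        design = CohortDesign(
            pd.DataFrame(rows, columns=["sample_id", "donor", "group", "time_h", "batch"])
            .set_index("sample_id")
        )
        m = ExpressionMatrix(
            pd.DataFrame([vals], index=["G00000"]).reindex(columns=design.sample_ids),
            stage="log2",
        )
        table = stats.differential_table(m, design)
        assert (table["median_log2fc"] == 1.0).all()

    def test_bh_adjustment_matches_stepup_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            from statsmodels.stats.multitest import multipletests

            got = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(got, bh_oracle(p), atol=1e-12)

    def test_bh_hand_example(self):
        assert np.allclose(bh_oracle([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_p_adj_never_below_p_raw(self, small_log2):
        log2m, design = small_log2
        table = stats.differential_table(log2m, design)
        assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()

    def test_empty_gated_set_yields_empty_table(self, small_log2):
        log2m, design = small_log2
        table = stats.differential_table(log2m, design, gated_features=[])
        assert table.empty

    def test_dropped_sample_leaves_other_time_points_bit_identical(self):
        cfg = simulate.SimulationConfig(n_features=80, n_mirnas=0, seed=51)
        m, design = latent_log2_cohort(cfg, [], np.random.default_rng(51))
        full = stats.differential_table(m, design)
        m2, d2 = simulate.drop_sample(m, design, "P5", 4.0)
        dropped = stats.differential_table(m2, d2)
        at4 = dropped[dropped["time_h"] == 4.0]
        assert (at4["n_pd"] == 4).all()
        for t in (0.0, 2.0, 8.0, 12.0, 24.0):
            a = full[full["time_h"] == t].reset_index(drop=True)
            b = dropped[dropped["time_h"] == t].reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)


def table_from_rows(rows):
    return pd.DataFrame(rows, columns=["feature_id", "time_h", "median_log2fc",
                                       "t_shrink", "p_raw", "p_adj", "n_pd", "n_hc"])


class TestClassifyCore:
    def test_early_window_increased_pattern(self):
        # significant with positive FC at 0 and 2 h only (TNFRSF8-like)
        rows = [("g", t, fc, 1.0, p, p, 5, 5) for t, fc, p in
                [(0, 1.16, 0.009), (2, 2.18, 0.0495), (4, 0.2, 0.5),
                 (8, 0.1, 0.9), (12, 0.0, 0.9), (24, 0.1, 0.8)]]
        core = stats.classify_core(table_from_rows(rows))
        rec = core.iloc[0]
        assert rec["is_core"]
        assert rec["windows"] == "early"
        assert rec["direction"] == "increased"
        assert rec["recurrence"] == 2

    def test_sign_alternation_is_mixed(self):
        # up at 0 h, down at 4 h (VCAN1-like) -> mixed direction
        rows = [("g", t, fc, 1.0, p, p, 5, 5) for t, fc, p in
                [(0, 1.20, 0.0313), (2, 0.1, 0.6), (4, -0.66, 0.0486),
                 (8, 0.0, 1.0), (12, 0.0, 1.0), (24, 0.0, 1.0)]]
        core = stats.classify_core(table_from_rows(rows))
        assert core.iloc[0]["direction"] == "mixed"
        assert set(core.iloc[0]["windows"].split("+")) == {"early", "intermediary"}

    def test_all_three_windows(self):
        # significant at 2, 4 and 24 h (HCAR3-like) -> all phases
        rows = [("g", t, fc, 1.0, p, p, 5, 5) for t, fc, p in
                [(0, 0.1, 0.5), (2, 0.97, 0.0317), (4, 3.08, 0.02),
                 (8, 0.2, 0.4), (12, 0.1, 0.6), (24, 1.5, 0.0491)]]
        core = stats.classify_core(table_from_rows(rows))
        assert core.iloc[0]["windows"] == "early+intermediary+late"
        assert core.iloc[0]["recurrence"] == 3

    def test_non_core_feature(self):
        rows = [("g", t, 0.1, 0.5, 0.9, 0.9, 5, 5) for t in (0, 2, 4, 8, 12, 24)]
        core = stats.classify_core(table_from_rows(rows))
        assert not core.iloc[0]["is_core"]
        assert core.iloc[0]["recurrence"] == 0

    def test_venn_counts_sum_to_core_total(self, small_log2):
        log2m, design = small_log2
        gate = stats.timecourse_gate(log2m, design)
        table = stats.differential_table(
            log2m, design, gated_features=gate.index[gate["passes_tc_gate"]]
        )
        core = stats.classify_core(table)
        venn = stats.window_venn(core)
        assert sum(venn.values()) == core["is_core"].sum()

    def test_core_features_subset_of_gated(self, small_log2):
        log2m, design = small_log2
        gate = stats.timecourse_gate(log2m, design)
        gated = set(gate.index[gate["passes_tc_gate"]])
        table = stats.differential_table(log2m, design, gated_features=sorted(gated))
        core = stats.classify_core(table)
        assert set(core.loc[core["is_core"], "feature_id"]) <= gated


class TestMarkerQC:
    def _design(self):
        from tck.containers import CohortDesign

        rows = []
        for g, pre in (("PD", "P"), ("HC", "C")):
            for d in range(1, 4):
                for t in (0.0, 2.0, 8.0):
                    rows.append((f"{pre}{d}_{t:g}h", f"{pre}{d}", g, t, "B1"))
        return CohortDesign(
            pd.DataFrame(rows, columns=["sample_id", "donor", "group", "time_h", "batch"])
            .set_index("sample_id")
        )

    def test_identical_groups_pass_with_p_one(self):
        design = self._design()
        t_of = design.table["time_h"].to_numpy()
        vals = np.where(t_of > 0, 8.0 + np.log2(1 + t_of), 8.0)
        m = ExpressionMatrix(
            pd.DataFrame([vals], index=["CD69"], columns=design.sample_ids),
            stage="log2",
        )
        qc = stats.marker_qc(m, design, ["CD69"])
        assert qc["qc_pass"]
        assert np.allclose(qc["table"]["p_unpaired_t"], 1.0)

    def test_flat_marker_fails_induction(self):
        design = self._design()
        m = ExpressionMatrix(
            pd.DataFrame(
                np.full((1, len(design.sample_ids)), 8.0),
                index=["CD69"], columns=design.sample_ids,
            ),
            stage="log2",
        )
        qc = stats.marker_qc(m, design, ["CD69"])
        assert not qc["induced"]
        assert not qc["qc_pass"]

    def test_missing_marker_marks_report_incomplete(self):
        design = self._design()
        m = ExpressionMatrix(
            pd.DataFrame(
                np.full((1, len(design.sample_ids)), 8.0),
                index=["CD69"], columns=design.sample_ids,
            ),
            stage="log2",
        )
        qc = stats.marker_qc(m, design, ["CD69", "IFIT3"])
        assert qc["markers_missing"] == ["IFIT3"]
        assert not qc["complete"]

    def test_equal_kinetics_pass_across_seeds(self):
        passes = 0
        for seed in range(5):
            cfg = simulate.SimulationConfig(n_features=50, n_mirnas=0,
                                            noise_sd=0.2, seed=60 + seed)
            signals = simulate.activation_marker_signals(cfg, n_markers=3)
            m, design = latent_log2_cohort(cfg, signals, np.random.default_rng(60 + seed))
            qc = stats.marker_qc(m, design, [s.feature_id for s in signals])
            passes += qc["qc_pass"]
        assert passes >= 4
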