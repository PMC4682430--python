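"""One-colour flag rules, filtering, normalization, and DEG calling."""

import math

import numpy as np
import pandas as pd
import pytest

from boltchip import expression
from boltchip.expression import (
    PipelineError,
    call_differential,
    cluster_features,
    evaluate_flags,
    filter_probes,
    flag_table,
    normalize_one_colour,
)

SAMPLES = ["R1", "R2", "R3", "S1", "S2", "S3"]


def _flags_frame(pass_map: dict[str, list[bool]]) -> pd.DataFrame:
    rows = []
    for probe, passes in pass_map.items():
        for sample, ok in zip(SAMPLES, passes):
            rows.append({"probe_id": probe, "sample_id": sample, "pass_all": ok})
    return pd.DataFrame(rows)


class TestFlags:
    @pytest.mark.parametrize(
        "bg_sub,bg_sd,expected",
        [
            (79.0, 30.0, True),  # 79 > 2.6 * 30 = 78
            (78.0, 30.0, False),  # strict inequality at the boundary
            (0.0, 30.0, False),
            (10.0, 0.0, True),
        ],
    )
    def test_above_background_rule(self, bg_sub, bg_sd, expected):
        assert evaluate_flags(bg_sub, bg_sd).above_background is expected

    def test_saturation_and_outlier_fail_pass_all(self):
        assert evaluate_flags(100.0, 1.0, is_saturated=True).pass_all is False
        assert evaluate_flags(100.0, 1.0, is_nonuniform_outlier=True).pass_all is False
        assert evaluate_flags(100.0, 1.0).pass_all is True

    def test_missing_values_fail(self):
        assert evaluate_flags(float("nan"), 1.0).above_background is False
        assert evaluate_flags(None, 1.0).above_background is False

    def test_k_monotonicity(self, rng):
        """Lowering the background multiplier never shrinks the retained set."""
        n = 300
        table = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(n)],
                "sample_id": "R1",
                "bg_sub_signal": rng.uniform(0, 100, n),
                "bg_sd": rng.uniform(0, 40, n),
                "is_saturated": False,
                "is_nonuniform_outlier": False,
            }
        )
        previous = None
        for k in (3.5, 2.6, 1.5, 0.5):
            passed = set(table.loc[flag_table(table, k=k)["pass_all"], "probe_id"])
            if previous is not None:
                assert previous <= passed
            previous = passed


class TestFilter:
    def test_pass_in_one_full_condition_is_retained(self, design_sheet):
        flags = _flags_frame({"p1": [True, True, True, True, False, True]})
        assert list(filter_probes(flags, design_sheet)) == ["p1"]

    def test_pass_everywhere_is_retained(self, design_sheet):
        flags = _flags_frame({"p1": [True] * 6})
        assert list(filter_probes(flags, design_sheet)) == ["p1"]

    def test_failure_in_each_condition_is_dropped(self, design_sheet):
        flags = _flags_frame({"p1": [False, True, True, True, True, False]})
        assert list(filter_probes(flags, design_sheet)) == []

    def test_missing_measurement_counts_as_failure(self, design_sheet):
        # passes wherever measured, but R1 is absent and S3 fails: neither
        # condition is fully covered by passing replicates
        flags = _flags_frame({"p1": [True, True, True, True, True, False]}).iloc[1:]
        assert list(filter_probes(flags, design_sheet)) == []

    def test_empty_condition_rejected(self, design_sheet):
        flags = _flags_frame({"p1": [True] * 6})
        with pytest.raises(PipelineError):
            filter_probes(flags, design_sheet.assign(condition="R"))


class TestNormalization:
    def test_constant_matrix_goes_to_zero(self):
        raw = pd.DataFrame(5.0, index=["a", "b"], columns=["s1", "s2", "s3"])
        out = normalize_one_colour(raw)
        assert np.allclose(out.values.to_numpy(), 0.0)

    def test_chip_scale_invariance(self):
        raw = pd.DataFrame(
            {"s1": [8.0, 2.0, 4.0], "s2": [2.0, 8.0, 4.0]}, index=["a", "b", "c"]
        )
        scaled = raw.copy()
        scaled["s1"] *= 10.0
        assert np.allclose(
            normalize_one_colour(raw).values.to_numpy(),
            normalize_one_colour(scaled).values.to_numpy(),
        )

    def test_hand_worked_two_by_two(self):
        # chip p75 = 6.5 for both samples; probe medians then 5/6.5 each;
        # entries become 8/5 and 2/5 before the log.
        raw = pd.DataFrame({"s1": [8.0, 2.0], "s2": [2.0, 8.0]}, index=["a", "b"])
        out = normalize_one_colour(raw).values
        expected = np.array(
            [
                [math.log2(8 / 5), math.log2(2 / 5)],
                [math.log2(2 / 5), math.log2(8 / 5)],
            ]
        )
        assert np.allclose(out.to_numpy(), expected)
        # per-probe median is 1 on the linear scale after the centering step
        assert np.allclose(np.median(2.0 ** out.to_numpy(), axis=1), 1.0)

    def test_all_masked_probe_excluded(self):
        raw = pd.DataFrame({"s1": [8.0, -1.0], "s2": [2.0, 0.0]}, index=["a", "bad"])
        out = normalize_one_colour(raw)
        assert list(out.values.index) == ["a"]
        assert out.provenance["excluded_probes"] == ["bad"]


class TestDifferential:
    def _matrix(self, rows: dict[str, list[float]]) -> pd.DataFrame:
        return pd.DataFrame(rows, index=SAMPLES).T

    def test_identical_groups_yield_no_calls(self, design_sheet):
        matrix = self._matrix({f"g{i}": [1.0, 1.1, 0.9, 1.0, 1.1, 0.9] for i in range(20)})
        calls = call_differential(matrix, design_sheet)
        assert int(calls["significant"].sum()) == 0

    def test_planted_three_fold_shift_detected(self, design_sheet, rng):
        """Monte-Carlo check: a log2(3) shift at noise SD 0.2 is essentially
        always called, with the correct direction."""
        n_null, n_planted, hits = 500, 20, 0
        values = rng.normal(0.0, 0.2, size=(n_null + n_planted, 6))
        values[:n_planted, 3:] += math.log2(3)
        matrix = pd.DataFrame(values, index=[f"g{i}" for i in range(n_null + n_planted)], columns=SAMPLES)
        calls = call_differential(matrix, design_sheet)
        planted = calls.iloc[:n_planted]
        hits = int(planted["significant"].sum())
        assert hits >= 18
        assert (planted.loc[planted["significant"], "direction"] == "up_in_S").all()
        assert planted["fold_change"].median() == pytest.approx(3.0, rel=0.2)

    def test_fold_change_gate_blocks_small_effects(self, design_sheet):
        # shift of log2(1.5) with near-zero noise: tiny p but FC < 2
        base = [0.0, 0.001, -0.001]
        shifted = [x + math.log2(1.5) for x in base]
        matrix = self._matrix({"g0": base + shifted})
        calls = call_differential(matrix, design_sheet)
        assert calls.loc["g0", "p_raw"] < 1e-6
        assert calls.loc["g0", "fold_change"] == pytest.approx(1.5, rel=1e-6)
        assert not bool(calls.loc["g0", "significant"])

    def test_zero_variance_equal_means_gives_p_one(self, design_sheet):
        matrix = self._matrix({"g0": [1.0] * 6, "g1": [0.0] * 3 + [2.0] * 3})
        calls = call_differential(matrix, design_sheet)
        assert calls.loc["g0", "p_raw"] == 1.0
        assert calls.loc["g1", "p_raw"] == 0.0
        assert bool(calls.loc["g1", "significant"])

    def test_adjusted_p_not_below_raw(self, design_sheet, rng):
        matrix = pd.DataFrame(
            rng.normal(size=(50, 6)), index=[f"g{i}" for i in range(50)], columns=SAMPLES
        )
        calls = call_differential(matrix, design_sheet)
        assert (calls["p_adj"] >= calls["p_raw"] - 1e-12).all()
        assert (calls["fold_change"] >= 1.0).all()

    def test_direction_matches_sign_of_difference(self, design_sheet):
        matrix = self._matrix({"up_s": [0.0] * 3 + [2.0] * 3, "up_r": [2.0] * 3 + [0.0] * 3})
        calls = call_differential(matrix, design_sheet)
        assert calls.loc["up_s", "direction"] == "up_in_S"
        assert calls.loc["up_r", "direction"] == "up_in_R"


class TestClustering:
    def test_identical_profiles_merge_at_zero(self):
        matrix = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], [4.0, 1.0, 2.0, 9.0]],
            index=["a", "b", "c"],
        )
        result = cluster_features(matrix)
        assert result.merge_tree[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_at_distance_two(self):
        profile = np.array([1.0, 2.0, 0.5, 3.0])
        matrix = pd.DataFrame([profile, -profile], index=["a", "b"])
        result = cluster_features(matrix)
        assert result.merge_tree[0, 2] == pytest.approx(2.0)

    def test_two_planted_blocks_separate(self):
        base1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        base2 = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        matrix = pd.DataFrame(
            [base1, base1 * 2 + 0.1, base2, base2 * 3 - 0.2],
            index=["a1", "a2", "b1", "b2"],
        )
        result = cluster_features(matrix)
        order = result.leaf_order
        block_a = {order.index("a1"), order.index("a2")}
        assert block_a in ({0, 1}, {2, 3})

    def test_zero_variance_rows_dropped_with_warning(self):
        matrix = pd.DataFrame(
            [[1.0, 2.0, 3.0], [0.0, 0.0, 0.0], [3.0, 1.0, 2.0]], index=["a", "flat", "b"]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            result = cluster_features(matrix)
        assert "flat" not in result.labels

    def test_single_item_rejected(self):
        with pytest.raises(PipelineError):
            cluster_features(pd.DataFrame([[1.0, 2.0, 3.0]], index=["only"]))

    def test_newick_output_contains_all_leaves(self):
        matrix = pd.DataFrame(
            np.arange(12, dtype=float).reshape(4, 3) ** 2, index=list("abcd")
        )
        newick = cluster_features(matrix).to_newick()
        assert newick.endswith(";")
        assert all(leaf in newick for leaf in "abcd")
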