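"""DEMS intersection, correlations, organelle track, and locus detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from boltchip.integration import (
    CODING_FEATURES,
    IntegrationError,
    MitoTrack,
    compare_platform_fold_changes,
    compare_track_groups,
    find_dems,
    find_dmr_rich_loci,
    meth_expr_correlation,
    mito_methylome_profile,
)

SAMPLES = ["R1", "R2", "R3", "S1", "S2", "S3"]


def _calls(ids, significant, direction="up_in_S"):
    return pd.DataFrame(
        {
            "significant": [i in set(significant) for i in ids],
            "direction": direction,
        },
        index=pd.Index(ids, name="sequence_id"),
    )


class TestFindDems:
    def test_disjoint_call_sets_give_empty(self):
        degs = _calls(["a", "b"], ["a", "b"])
        dmrs = _calls(["c", "d"], ["c", "d"])
        assert len(find_dems(degs, dmrs)) == 0

    def test_planted_joint_recovered_exactly(self, rng):
        ids = [f"s{i:02d}" for i in range(40)]
        joint = ["s00", "s03", "s07", "s11", "s20", "s31"]
        deg_only = ["s01", "s02", "s04", "s05", "s06", "s08", "s09", "s10",
                    "s12", "s13", "s14", "s15", "s16", "s17"]
        dmr_only = ["s21", "s22", "s23", "s24", "s25", "s26", "s27", "s28", "s29"]
        degs = _calls(ids, joint + deg_only)  # 20 DEGs
        dmrs = _calls(ids, joint + dmr_only, direction="hyper_in_S")  # 15 DMRs
        dems = find_dems(degs, dmrs)
        assert list(dems.index) == sorted(joint)

    def test_symmetric_and_bounded(self, rng):
        ids = [f"s{i}" for i in range(30)]
        deg_sig = list(rng.choice(ids, 12, replace=False))
        dmr_sig = list(rng.choice(ids, 9, replace=False))
        degs, dmrs = _calls(ids, deg_sig), _calls(ids, dmr_sig)
        forward = find_dems(degs, dmrs)
        backward = find_dems(dmrs, degs)
        assert list(forward.index) == list(backward.index)
        assert len(forward) <= min(len(deg_sig), len(dmr_sig))

    def test_values_attached_with_group_means(self):
        ids = ["a", "b"]
        degs, dmrs = _calls(ids, ["a"]), _calls(ids, ["a"], direction="hyper_in_S")
        em = pd.DataFrame([[1.0] * 3 + [3.0] * 3], index=["a"], columns=SAMPLES)
        mm = pd.DataFrame([[0.5] * 3 + [2.5] * 3], index=["a"], columns=SAMPLES)
        dems = find_dems(degs, dmrs, em, mm)
        assert dems.loc["a", "expr_S"] == pytest.approx(3.0)
        assert dems.loc["a", "expr_R"] == pytest.approx(1.0)
        assert dems.loc["a", "meth_S"] == pytest.approx(2.5)

    def test_missing_matrix_values_rejected(self):
        degs, dmrs = _calls(["a"], ["a"]), _calls(["a"], ["a"])
        em = pd.DataFrame(columns=SAMPLES, dtype=float)
        with pytest.raises(IntegrationError, match="lacks values"):
            find_dems(degs, dmrs, em, None)


class TestCorrelation:
    def _records(self, meth, expr):
        frame = pd.DataFrame({"meth_S": meth, "expr_S": expr})
        frame["meth_R"] = np.nan
        frame["expr_R"] = np.nan
        return frame

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        records = pd.DataFrame(
            {"meth_S": x, "expr_S": -x, "meth_R": x, "expr_R": -x}
        )
        result = meth_expr_correlation(records, level="group_mean")
        assert result.pearson_r == pytest.approx(-1.0)
        assert result.spearman_rho == pytest.approx(-1.0)

    def test_dems_fixture_group_means_match_frozen_oracle(self):
        """28 group-mean pairs from the packaged joint-call table; expected
        values frozen from a from-scratch covariance/rank computation."""
        from boltchip.fixtures import load_dems_table

        table = load_dems_table()
        result = meth_expr_correlation(table, level="group_mean")
        assert result.n == 28
        assert result.pearson_r == pytest.approx(-0.35039382896650134)
        assert result.spearman_rho == pytest.approx(-0.33967690210996737)
        assert result.pearson_r < 0 and result.spearman_rho < 0

    def test_constant_column_rejected(self):
        records = pd.DataFrame(
            {"meth_S": [1.0, 1.0, 1.0], "expr_S": [1.0, 2.0, 3.0],
             "meth_R": [1.0, 1.0, 1.0], "expr_R": [3.0, 2.0, 1.0]}
        )
        with pytest.raises(IntegrationError, match="zero variance"):
            meth_expr_correlation(records, level="group_mean")

    def test_spearman_invariant_to_monotone_transform(self):
        meth = np.array([0.1, 0.9, 0.4, 0.7, 0.2, 0.6])
        expr = np.array([2.0, -1.0, 1.0, -0.5, 1.5, 0.0])
        base = pd.DataFrame({f"meth_{s}": m for s, m in zip(SAMPLES, meth)} |
                            {f"expr_{s}": e for s, e in zip(SAMPLES, expr)}, index=["seq"])
        warped = base.copy()
        for s in SAMPLES:
            warped[f"meth_{s}"] = np.exp(3.0 * warped[f"meth_{s}"])
        r1 = meth_expr_correlation(base, level="per_genotype")
        r2 = meth_expr_correlation(warped, level="per_genotype")
        assert r1.spearman_rho == pytest.approx(r2.spearman_rho)


class TestPlatformComparison:
    def test_identical_vectors(self):
        fc = pd.Series([2.0, 3.0, 0.5, 1.5], index=list("abcd"))
        assert compare_platform_fold_changes(fc, fc).pearson_r == pytest.approx(1.0)

    def test_scaling_invariance(self):
        fc = pd.Series([2.0, 3.0, 0.5, 1.5], index=list("abcd"))
        assert compare_platform_fold_changes(fc, fc * 2.0).pearson_r == pytest.approx(1.0)

    def test_noisy_copy_strongly_correlated(self, rng):
        log_fc = np.array([1.0, -1.5, 2.0, -0.5, 1.6, -2.2])
        fc_a = pd.Series(2.0 ** log_fc, index=[f"g{i}" for i in range(6)])
        fc_b = pd.Series(2.0 ** (log_fc + rng.normal(0, 0.1, 6)), index=fc_a.index)
        result = compare_platform_fold_changes(fc_a, fc_b)
        # independent oracle on the same draws
        expected = stats.pearsonr(log_fc, np.log2(fc_b.to_numpy())).statistic
        assert result.pearson_r == pytest.approx(expected)
        assert result.pearson_r > 0.9

    def test_too_few_shared_genes_rejected(self):
        a = pd.Series([1.0, 2.0], index=["a", "b"])
        b = pd.Series([1.0, 2.0], index=["a", "c"])
        with pytest.raises(IntegrationError):
            compare_platform_fold_changes(a, b)


def _track(values_r, values_s, positions=None, coding=None, length=100_000):
    n = len(values_r)
    positions = np.asarray(positions if positions is not None else np.arange(n) * 100)
    coding = np.asarray(coding if coding is not None else [False] * n)
    return MitoTrack(
        positions=positions,
        mean_r=np.asarray(values_r, dtype=float),
        mean_s=np.asarray(values_s, dtype=float),
        is_coding=coding,
        genome_length=length,
        coding_intervals=np.empty((0, 2), int),
    )


class TestMitoProfile:
    def _inputs(self, design_sheet, n=50, genome_length=10_000):
        ids = [f"MT:{i * 100:05d}" for i in range(n)]
        coords = pd.Series([i * 100 for i in range(n)], index=ids)
        annotation = pd.DataFrame(
            {
                "Chromosome": "MITO",
                "Feature": ["ORF", "tRNA", "CpG_island"],
                "Start": [0, 2000, 5000],
                "End": [1000, 2500, 5400],
            }
        )
        return ids, coords, annotation

    def test_constant_ratios_give_flat_partitioned_track(self, design_sheet):
        ids, coords, annotation = self._inputs(design_sheet)
        matrix = pd.DataFrame(0.25, index=ids, columns=SAMPLES)
        track = mito_methylome_profile(matrix, coords, annotation, design_sheet, 10_000)
        assert np.allclose(track.mean_r, 0.25) and np.allclose(track.mean_s, 0.25)
        overall = track.mean_overall
        assert overall[track.is_coding].mean() == pytest.approx(
            overall[~track.is_coding].mean()
        )
        # coding partition = ORF [0,1000) + tRNA [2000,2500): probes whose
        # 60-mer interval overlaps, i.e. starts < 1000, and 1960 <= start < 2500
        expected_coding = sum(
            1 for p in track.positions if p < 1000 or 1960 <= p < 2500
        )
        assert int(track.is_coding.sum()) == expected_coding

    def test_noncoding_offset_recovered(self, design_sheet):
        ids, coords, annotation = self._inputs(design_sheet)
        matrix = pd.DataFrame(0.0, index=ids, columns=SAMPLES)
        track0 = mito_methylome_profile(matrix, coords, annotation, design_sheet, 10_000)
        matrix.loc[~pd.Series(track0.is_coding, index=ids), :] += 0.5
        track = mito_methylome_profile(matrix, coords, annotation, design_sheet, 10_000)
        overall = track.mean_overall
        diff = overall[~track.is_coding].mean() - overall[track.is_coding].mean()
        assert diff == pytest.approx(0.5)

    def test_group_offset_everywhere(self, design_sheet):
        ids, coords, annotation = self._inputs(design_sheet)
        matrix = pd.DataFrame(0.0, index=ids, columns=SAMPLES)
        matrix[["R1", "R2", "R3"]] += 0.3
        track = mito_methylome_profile(matrix, coords, annotation, design_sheet, 10_000)
        assert (track.mean_r > track.mean_s).all()

    def test_probe_without_coordinate_excluded(self, design_sheet):
        ids, coords, annotation = self._inputs(design_sheet)
        matrix = pd.DataFrame(0.0, index=ids + ["orphan"], columns=SAMPLES)
        track = mito_methylome_profile(matrix, coords, annotation, design_sheet, 10_000)
        assert "orphan" not in track.probe_ids

    def test_out_of_range_coordinate_rejected(self, design_sheet):
        ids, coords, annotation = self._inputs(design_sheet)
        coords.iloc[0] = 99_999
        matrix = pd.DataFrame(0.0, index=ids, columns=SAMPLES)
        with pytest.raises(IntegrationError):
            mito_methylome_profile(matrix, coords, annotation, design_sheet, 10_000)


class TestTrackContrasts:
    def test_identical_groups_p_near_one(self):
        values = np.linspace(-1, 1, 60)
        result = compare_track_groups(_track(values, values.copy()), "R_vs_S")
        assert result["p_value"] > 0.99 or np.isnan(result["p_value"])

    def test_planted_r_over_s(self, rng):
        noise = rng.normal(0, 0.1, 500)
        base = rng.normal(0, 0.3, 500)
        result = compare_track_groups(_track(base + 0.3 + noise, base), "R_vs_S")
        assert result["p_value"] < 0.001
        assert result["direction"] == "R>S"

    def test_planted_noncoding_over_coding(self, rng):
        n = 400
        coding = np.zeros(n, dtype=bool)
        coding[:150] = True
        values = rng.normal(0, 0.1, n)
        values[~coding] += 0.4
        result = compare_track_groups(_track(values, values, coding=coding), "coding_vs_noncoding")
        assert result["p_value"] < 0.01
        assert result["direction"] == "noncoding>coding"

    def test_sign_flip_permutation_null_is_uniform(self, rng):
        """Under a null track, the paired R-vs-S p-value is uniform across
        sign-flip permutations of the per-probe group difference."""
        diff = rng.normal(0, 0.1, 300)
        base = rng.normal(0, 0.3, 300)
        pvals = []
        for _ in range(200):
            flip = rng.random(300) < 0.5
            d = np.where(flip, -diff, diff)
            pvals.append(
                compare_track_groups(_track(base + d, base), "R_vs_S")["p_value"]
            )
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1

    def test_empty_side_rejected(self):
        values = np.zeros(20)
        with pytest.raises(IntegrationError):
            compare_track_groups(
                _track(values, values, coding=[True] * 20), "coding_vs_noncoding"
            )


class TestDmrRichLoci:
    def test_empty_input(self):
        assert find_dmr_rich_loci([]) == []

    def test_two_clusters_enumerated(self):
        positions = [1000, 2000, 3000, 50_000, 51_000, 52_000, 53_000]
        loci = find_dmr_rich_loci(positions, max_gap=5000, min_probes=3)
        assert [l.count for l in loci] == [3, 4]
        assert loci[0].start == 1000 and loci[0].end == 3060
        assert loci[1].start == 50_000 and loci[1].end == 53_060

    def test_uniform_sparse_positions_give_nothing(self):
        positions = list(range(0, 100_000, 10_000))
        assert find_dmr_rich_loci(positions, max_gap=5000, min_probes=3) == []

    def test_order_independent_and_disjoint(self, rng):
        positions = rng.integers(0, 200_000, 150).tolist()
        a = find_dmr_rich_loci(positions)
        b = find_dmr_rich_loci(list(reversed(positions)))
        assert [(l.start, l.end) for l in a] == [(l.start, l.end) for l in b]
        spans = sorted((l.start, l.end) for l in a)
        assert all(s2 >= e1 for (_, e1), (s2, _) in zip(spans, spans[1:]))
        assigned = [p for l in a for p in l.probe_ids]
        assert len(assigned) == len(set(assigned))
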