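"""Harmonization: I/O, lifting, standardization, QC, KNN, overlap."""

import numpy as np
import pandas as pd
import pytest

import protbridge as pb
from protbridge.harmonize import (
    HarmonizeError,
    PLATFORM_APTAMER,
    PLATFORM_PEA,
    _assay_distance_matrix,
    _pct_int,
    apply_scaler,
    resolve_duplicates,
)

from conftest import make_matrix


class TestExpressionMatrix:
    def test_rejects_unknown_platform_and_scale(self):
        df = pd.DataFrame([[1.0]], index=["S0"], columns=["a0"])
        with pytest.raises(HarmonizeError):
            pb.ExpressionMatrix(df, platform="mass_spec", scale="raw")
        with pytest.raises(HarmonizeError):
            pb.ExpressionMatrix(df, platform=PLATFORM_APTAMER, scale="cube_root")

    def test_rejects_duplicate_ids(self):
        df = pd.DataFrame([[1.0], [2.0]], index=["S0", "S0"], columns=["a0"])
        with pytest.raises(HarmonizeError):
            pb.ExpressionMatrix(df, platform=PLATFORM_APTAMER, scale="raw")
        df2 = pd.DataFrame([[1.0, 2.0]], index=["S0"], columns=["a0", "a0"])
        with pytest.raises(HarmonizeError):
            pb.ExpressionMatrix(df2, platform=PLATFORM_APTAMER, scale="raw")

    def test_missing_mask(self):
        m = make_matrix([[1.0, np.nan], [3.0, 4.0]], scale="log2")
        assert m.missing_mask.to_numpy().sum() == 1
        assert m.missing_mask.iloc[0, 1]


class TestReadMatrix:
    def test_na_token_round_trip(self, tmp_path):
        m = make_matrix([[1.0, np.nan], [3.0, 4.0]], platform=PLATFORM_PEA,
                        scale="log2")
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        assert "NA" in path.read_text()
        back = pb.read_matrix(path, platform=PLATFORM_PEA, scale="log2")
        pd.testing.assert_frame_equal(back.data, m.data, check_names=False)

    def test_non_numeric_values_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\ta0\nS0\toops\n")
        with pytest.raises(HarmonizeError, match="non-numeric"):
            pb.read_matrix(path, platform=PLATFORM_PEA, scale="log2")


class TestLiftPanel:
    def test_linear_transform_applied_per_assay(self):
        m = make_matrix([[2.0, 10.0], [4.0, 20.0]], scale="raw")
        lift = pd.DataFrame(
            {"assay_id": ["a0", "a1"], "scale": [2.0, 0.5], "offset": [1.0, 0.0]}
        )
        out = pb.lift_panel(m, lift)
        np.testing.assert_allclose(out.data.to_numpy(), [[5.0, 5.0], [9.0, 10.0]])

    def test_absent_assays_pass_through_with_warning(self):
        m = make_matrix([[2.0, 10.0]], scale="raw")
        lift = pd.DataFrame({"assay_id": ["a0"], "scale": [2.0], "offset": [0.0]})
        with pytest.warns(UserWarning, match="passed through"):
            out = pb.lift_panel(m, lift)
        np.testing.assert_allclose(out.data.to_numpy(), [[4.0, 10.0]])

    def test_requires_raw_scale_and_positive_lift_scale(self):
        lift = pd.DataFrame({"assay_id": ["a0"], "scale": [2.0], "offset": [0.0]})
        m_log = make_matrix([[2.0]], scale="log2")
        with pytest.raises(HarmonizeError, match="raw"):
            pb.lift_panel(m_log, lift)
        bad = pd.DataFrame({"assay_id": ["a0"], "scale": [-1.0], "offset": [0.0]})
        with pytest.raises(HarmonizeError, match="non-positive"):
            pb.lift_panel(make_matrix([[2.0]], scale="raw"), bad)


class TestLog2Standardize:
    def test_golden_powers_of_two(self):
        # log2(8,16,32) = (3,4,5): mean 4, SD 1 with the n-1 convention
        m = make_matrix([[8.0], [16.0], [32.0]], scale="raw")
        out, scaler = pb.log2_standardize(m)
        np.testing.assert_allclose(out.data["a0"].to_numpy(), [-1.0, 0.0, 1.0])
        assert scaler.means["a0"] == pytest.approx(4.0)
        assert scaler.sds["a0"] == pytest.approx(1.0)
        assert out.scale == "standardized"

    def test_fit_subset_parameters_apply_to_all_samples(self):
        m = make_matrix([[8.0], [16.0], [32.0], [1024.0]], scale="raw")
        out, _ = pb.log2_standardize(m, fit_subset=["S0", "S1", "S2"])
        # held-out sample standardized with training parameters: (10-4)/1
        assert out.data.loc["S3", "a0"] == pytest.approx(6.0)

    def test_log2_only_applied_to_raw(self):
        m = make_matrix([[3.0], [4.0], [5.0]], scale="log2")
        out, _ = pb.log2_standardize(m)
        np.testing.assert_allclose(out.data["a0"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_double_standardization_rejected(self):
        m = make_matrix([[1.0], [2.0]], scale="standardized")
        with pytest.raises(HarmonizeError, match="already standardized"):
            pb.log2_standardize(m)

    def test_nonpositive_raw_rejected(self):
        m = make_matrix([[-1.0], [2.0]], scale="raw")
        with pytest.raises(HarmonizeError, match="non-positive"):
            pb.log2_standardize(m)

    def test_zero_variance_assay_named_in_error(self):
        m = make_matrix([[5.0, 1.0], [5.0, 2.0]], scale="log2",
                        assay_ids=["flat", "ok"])
        with pytest.raises(HarmonizeError, match="flat"):
            pb.log2_standardize(m)

    def test_unknown_fit_subset_sample_rejected(self):
        m = make_matrix([[1.0], [2.0]], scale="log2")
        with pytest.raises(HarmonizeError, match="fit_subset"):
            pb.log2_standardize(m, fit_subset=["S0", "nope"])

    def test_apply_scaler_matches_refit(self):
        m = make_matrix([[8.0], [16.0], [32.0]], scale="raw")
        _, scaler = pb.log2_standardize(m)
        out = apply_scaler(make_matrix([[64.0]], scale="raw"), scaler)
        assert out.data.iloc[0, 0] == pytest.approx(2.0)


class TestQcMissingness:
    def test_boundary_is_strict(self):
        # a0 missing exactly 10% (1/10): retained; a1 missing 20%: dropped.
        # After dropping a1, S0 is missing 1 of the 10 kept assays (exactly
        # 10%), so the strict ">" rule retains it too.
        vals = np.ones((10, 11))
        vals[0, 0] = np.nan
        vals[:2, 1] = np.nan
        m = make_matrix(vals, platform=PLATFORM_PEA, scale="log2")
        out = pb.qc_missingness(m, threshold=0.10)
        assert "a1" not in out.assay_ids
        assert len(out.assay_ids) == 10
        assert out.n_samples == 10

    def test_assays_dropped_before_samples(self):
        # sample S0 is missing only in the bad assay; once that assay is
        # dropped S0 is clean and must survive
        vals = np.ones((5, 3))
        vals[:, 2] = np.nan  # fully missing assay
        vals[0, 2] = 1.0  # 80% missing -> dropped
        m = make_matrix(vals, platform=PLATFORM_PEA, scale="log2")
        out = pb.qc_missingness(m)
        assert out.assay_ids == ["a0", "a1"]
        assert out.n_samples == 5

    def test_sample_dropped_when_missing_across_kept_assays(self):
        # each assay is only 5% missing (retained) but S0 is missing half
        # of the retained panel, so the sample pass removes it
        vals = np.ones((20, 4))
        vals[0, :2] = np.nan
        m = make_matrix(vals, platform=PLATFORM_PEA, scale="log2")
        out = pb.qc_missingness(m)
        assert out.n_assays == 4
        assert "S0" not in out.sample_ids
        assert out.n_samples == 19

    def test_all_assays_failing_raises(self):
        vals = np.full((4, 2), np.nan)
        vals[0, :] = 1.0
        m = make_matrix(vals, platform=PLATFORM_PEA, scale="log2")
        with pytest.raises(HarmonizeError, match="every assay"):
            pb.qc_missingness(m)


class TestAssayDistance:
    def test_complete_data_matches_plain_euclidean(self, rng):
        x = rng.standard_normal((20, 4))
        d = _assay_distance_matrix(x)
        for i in range(4):
            for j in range(4):
                expect = np.sqrt(((x[:, i] - x[:, j]) ** 2).sum())
                # matrix-algebra formulation carries ~1e-8 cancellation noise
                assert d[i, j] == pytest.approx(expect, abs=1e-6)

    def test_missingness_rescaling(self):
        # columns share 2 of 4 samples; distance over shared entries is
        # rescaled by n_samples / n_shared = 2
        x = np.array(
            [[0.0, 1.0], [0.0, 1.0], [np.nan, 5.0], [0.0, np.nan]]
        )
        d = _assay_distance_matrix(x)
        assert d[0, 1] == pytest.approx(np.sqrt(4 / 2 * (1 + 1)))

    def test_no_shared_samples_gives_inf(self):
        x = np.array([[1.0, np.nan], [np.nan, 2.0]])
        d = _assay_distance_matrix(x)
        assert np.isinf(d[0, 1])


class TestKnnImpute:
    def test_hole_filled_with_mean_of_nearest_observed_assays(self):
        # a0 has a hole at S0; nearest assays by distance are a1 then a2
        vals = np.array(
            [
                [np.nan, 2.0, 4.0, 100.0],
                [1.0, 1.1, 3.0, 100.0],
                [2.0, 2.1, 4.0, 100.0],
                [3.0, 3.1, 5.0, 100.0],
            ]
        )
        m = make_matrix(vals, platform=PLATFORM_PEA, scale="log2")
        out = pb.knn_impute(m, k=2)
        assert out.data.iloc[0, 0] == pytest.approx((2.0 + 4.0) / 2)
        # observed entries are untouched
        assert out.data.iloc[1, 0] == 1.0

    def test_k_one_copies_single_nearest_donor(self):
        vals = np.array([[np.nan, 7.0, 50.0], [1.0, 1.0, 50.0], [2.0, 2.0, 50.0]])
        m = make_matrix(vals, platform=PLATFORM_PEA, scale="log2")
        out = pb.knn_impute(m, k=1)
        assert out.data.iloc[0, 0] == 7.0

    def test_k_larger_than_panel_warns_and_uses_all(self):
        vals = np.array([[np.nan, 2.0], [1.0, 1.0], [3.0, 3.0]])
        m = make_matrix(vals, platform=PLATFORM_PEA, scale="log2")
        with pytest.warns(UserWarning, match="exceeds"):
            out = pb.knn_impute(m, k=10)
        assert out.data.iloc[0, 0] == 2.0

    def test_no_usable_donor_falls_back_to_assay_mean(self):
        # S0 observed nowhere else, so a0's own mean fills the hole
        vals = np.array([[np.nan, np.nan], [1.0, 5.0], [3.0, 6.0]])
        m = make_matrix(vals, platform=PLATFORM_PEA, scale="log2")
        out = pb.knn_impute(m, k=1)
        assert out.data.iloc[0, 0] == pytest.approx(2.0)
        assert out.data.iloc[0, 1] == pytest.approx(5.5)

    def test_fully_missing_assay_raises(self):
        vals = np.array([[np.nan, 1.0], [np.nan, 2.0]])
        m = make_matrix(vals, platform=PLATFORM_PEA, scale="log2")
        with pytest.raises(HarmonizeError, match="no observed"):
            pb.knn_impute(m)

    def test_complete_matrix_returned_unchanged(self, rng):
        m = make_matrix(rng.standard_normal((6, 3)), platform=PLATFORM_PEA,
                        scale="log2")
        out = pb.knn_impute(m)
        pd.testing.assert_frame_equal(out.data, m.data)


class TestResolveDuplicates:
    def _amap(self):
        return pd.DataFrame(
            {
                "assay_id": ["p1_B", "p1_2_B", "p2_B"],
                "platform": [PLATFORM_PEA] * 3,
                "protein_id": ["p1", "p1", "p2"],
            }
        )

    def test_lowest_missing_fraction_wins(self):
        vals = np.array(
            [[np.nan, 1.0, 9.0], [2.0, 2.0, 9.0], [np.nan, 3.0, 9.0]]
        )
        m = make_matrix(vals, platform=PLATFORM_PEA, scale="log2",
                        assay_ids=["p1_B", "p1_2_B", "p2_B"])
        out = resolve_duplicates(m, self._amap())
        assert out.assay_ids == ["p1_2_B", "p2_B"]

    def test_tie_breaks_lexicographically(self):
        vals = np.ones((3, 3))
        m = make_matrix(vals, platform=PLATFORM_PEA, scale="log2",
                        assay_ids=["p1_B", "p1_2_B", "p2_B"])
        out = resolve_duplicates(m, self._amap())
        assert out.assay_ids == ["p1_2_B", "p2_B"]  # "p1_2_B" < "p1_B"

    def test_premask_decides_not_post_imputation_values(self):
        vals = np.ones((4, 3))  # already imputed: no NaN left
        premask = pd.DataFrame(
            False, index=[f"S{i}" for i in range(4)],
            columns=["p1_B", "p1_2_B", "p2_B"],
        )
        premask.loc["S0", "p1_2_B"] = True
        m = make_matrix(vals, platform=PLATFORM_PEA, scale="log2",
                        assay_ids=["p1_B", "p1_2_B", "p2_B"])
        out = resolve_duplicates(m, self._amap(), premask=premask)
        assert out.assay_ids == ["p1_B", "p2_B"]

    def test_aptamer_matrix_passes_through(self):
        m = make_matrix(np.ones((2, 2)), platform=PLATFORM_APTAMER, scale="raw",
                        assay_ids=["p1_A", "p1_2_A"])
        amap = pd.DataFrame(
            {"assay_id": ["p1_A", "p1_2_A"], "platform": [PLATFORM_APTAMER] * 2,
             "protein_id": ["p1", "p1"]}
        )
        out = resolve_duplicates(m, amap)
        assert out.assay_ids == ["p1_A", "p1_2_A"]


class TestBuildOverlap:
    def test_counts_and_rounding_convention(self):
        assert _pct_int(34.92) == 35
        assert _pct_int(60.50) == 60  # one decimal then ties-to-even

    def test_overlap_rows_and_coverage(self):
        map_a = pd.DataFrame(
            {
                "assay_id": ["p1_A", "p1_2_A", "p2_A", "p3_A"],
                "platform": [PLATFORM_APTAMER] * 4,
                "protein_id": ["p1", "p1", "p2", "p3"],
            }
        )
        map_b = pd.DataFrame(
            {
                "assay_id": ["p1_B", "p2_B", "p4_B"],
                "platform": [PLATFORM_PEA] * 3,
                "protein_id": ["p1", "p2", "p4"],
            }
        )
        overlap, summary = pb.build_overlap(map_a, map_b)
        # p1 contributes two rows (two aptamer reagents), p2 one row
        assert len(overlap) == 3
        assert summary["n_overlap_proteins"] == 2
        assert summary["coverage_pct_A"] == _pct_int(100 * 2 / 4)
        assert summary["coverage_pct_B"] == _pct_int(100 * 2 / 3)

    def test_unresolved_pea_duplicates_rejected(self):
        map_a = pd.DataFrame(
            {"assay_id": ["p1_A"], "platform": [PLATFORM_APTAMER],
             "protein_id": ["p1"]}
        )
        map_b = pd.DataFrame(
            {"assay_id": ["p1_B", "p1_2_B"], "platform": [PLATFORM_PEA] * 2,
             "protein_id": ["p1", "p1"]}
        )
        with pytest.raises(HarmonizeError, match="resolve duplicates"):
            pb.build_overlap(map_a, map_b)


class TestHarmonizePair:
    def test_end_to_end_on_simulated_data(self, small_sim_config):
        truth, mat_a, mat_b, _ = pb.simulate_dataset(small_sim_config)
        map_a, map_b = pb.assay_maps(truth)
        amap = pd.concat([map_a, map_b], ignore_index=True)
        fit = truth.sample_ids[:200]
        a_std, b_std, scaler_a, scaler_b = pb.harmonize_pair(
            mat_a, mat_b, amap, fit_subset=fit
        )
        assert a_std.sample_ids == b_std.sample_ids
        assert a_std.scale == b_std.scale == "standardized"
        assert not b_std.missing_mask.to_numpy().any()
        # training-subset means ~0, SDs ~1 under the fitted scalers
        surviving_fit = [s for s in fit if s in a_std.data.index]
        np.testing.assert_allclose(
            a_std.data.loc[surviving_fit].mean(), 0.0, atol=1e-9
        )
        np.testing.assert_allclose(
            a_std.data.loc[surviving_fit].std(ddof=1), 1.0, atol=1e-9
        )

    def test_platform_order_enforced(self, small_sim_config):
        truth, mat_a, mat_b, _ = pb.simulate_dataset(small_sim_config)
        map_a, map_b = pb.assay_maps(truth)
        amap = pd.concat([map_a, map_b], ignore_index=True)
        with pytest.raises(HarmonizeError, match="expects"):
            pb.harmonize_pair(mat_b, mat_a, amap)
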