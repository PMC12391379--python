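"""SAF counting, min-read filtering, TMM, CPM, Grubbs and differential TE."""

import numpy as np
import pandas as pd
import pytest

from riboshift.quant import (
    OrfCountMatrix,
    cpm,
    count_features,
    delta_te,
    filter_min_reads,
    grubbs_outliers,
    read_saf,
    tmm_factors,
    translation_efficiency,
)

from _oracles import fisher_two_sided, grubbs_critical, tmm_reference


def _saf_frame(rows):
    return pd.DataFrame(rows, columns=["GeneID", "Chr", "Start", "End", "Strand"])


class TestCounting:
    def test_saf_boundary_inclusive(self):
        saf = _saf_frame([("F1", "T1", 100, 200, "+")])
        psites = {"s1": pd.DataFrame({"chrom": ["T1", "T1", "T1"], "pos": [99, 199, 200]})}
        cm = count_features(psites, saf)
        # 0-based 99 == Start-1 counted; 199 == End-1 counted; 200 not
        assert cm.counts[0, 0] == 2

    def test_rows_sharing_geneid_summed(self):
        saf = _saf_frame([("F1", "T1", 1, 10, "+"), ("F1", "T1", 21, 30, "+")])
        psites = {"s1": pd.DataFrame({"chrom": ["T1"] * 3, "pos": [5, 25, 15]})}
        cm = count_features(psites, saf)
        assert cm.feature_ids == ["F1"]
        assert cm.counts[0, 0] == 2

    def test_malformed_saf_reports_line(self, tmp_path):
        path = tmp_path / "bad.saf"
        path.write_text("F1\tT1\t10\t20\t+\nF2\tT1\tten\t20\t+\n")
        with pytest.raises(ValueError, match="line 2"):
            read_saf(path)

    def test_saf_roundtrip(self, tmp_path):
        path = tmp_path / "ok.saf"
        path.write_text("GeneID\tChr\tStart\tEnd\tStrand\nF1\tT1\t10\t20\t+\n")
        df = read_saf(path)
        assert len(df) == 1 and df.Start.iloc[0] == 10

    def test_library_sizes_are_column_sums(self):
        cm = OrfCountMatrix(["a", "b"], ["x", "y"], np.array([[1, 2], [3, 4]]))
        assert (cm.library_sizes == [4, 6]).all()


class TestFilter:
    def test_boundary_kept(self):
        cm = OrfCountMatrix(["f"], ["a", "b", "c"], np.array([[5, 5, 5]]))
        assert filter_min_reads(cm, 5).feature_ids == ["f"]

    def test_per_sample_rule_removes(self):
        cm = OrfCountMatrix(["f"], ["a", "b", "c"], np.array([[10, 4, 10]]))
        with pytest.warns(UserWarning):
            assert filter_min_reads(cm, 5).feature_ids == []

    def test_threshold_zero_is_identity(self):
        cm = OrfCountMatrix(["f", "g"], ["a"], np.array([[0], [7]]))
        assert filter_min_reads(cm, 0).feature_ids == ["f", "g"]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        cm = OrfCountMatrix(
            [f"f{i}" for i in range(30)],
            ["a", "b"],
            rng.integers(0, 20, size=(30, 2)),
        )
        once = filter_min_reads(cm, 5)
        twice = filter_min_reads(once, 5)
        assert once.feature_ids == twice.feature_ids


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(np.arange(1, 31)[:, None], (1, 3))
        cm = OrfCountMatrix([f"f{i}" for i in range(30)], ["a", "b", "c"], counts)
        np.testing.assert_allclose(tmm_factors(cm), 1.0)

    def test_scaled_column_absorbed_by_library_size(self):
        rng = np.random.default_rng(2)
        a = rng.integers(10, 200, size=40)
        counts = np.column_stack([a, 2 * a])
        cm = OrfCountMatrix([f"f{i}" for i in range(40)], ["a", "b"], counts)
        np.testing.assert_allclose(tmm_factors(cm), 1.0, atol=1e-12)

    def test_matches_independent_reference(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            counts = rng.negative_binomial(4, 0.02, size=(50, 4))
            counts[counts == 0] += rng.integers(0, 2, size=(counts == 0).sum())
            cm = OrfCountMatrix(
                [f"f{i}" for i in range(50)], list("abcd"), counts
            )
            np.testing.assert_allclose(
                tmm_factors(cm), tmm_reference(counts), atol=1e-9
            )

    def test_matches_edger_frozen_fixture(self):
        """Factors for a deterministic 50×4 matrix frozen from
        edgeR::calcNormFactors(method='TMM')."""
        rng = np.random.default_rng(20240501)
        counts = rng.negative_binomial(5, 0.05, size=(50, 4))
        cm = OrfCountMatrix([f"g{i}" for i in range(50)], list("abcd"), counts)
        expected = [1.058013990854, 0.984672753792, 0.967869961824, 0.991744171226]
        np.testing.assert_allclose(tmm_factors(cm), expected, atol=1e-9)

    def test_geometric_mean_one_and_order_invariance(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 500, size=(60, 3))
        cm = OrfCountMatrix([f"f{i}" for i in range(60)], list("abc"), counts)
        f1 = tmm_factors(cm)
        assert abs(np.exp(np.mean(np.log(f1))) - 1.0) < 1e-9
        perm = rng.permutation(60)
        cm2 = OrfCountMatrix(
            [f"f{i}" for i in perm], list("abc"), counts[perm]
        )
        np.testing.assert_allclose(tmm_factors(cm2), f1, atol=1e-12)

    def test_no_shared_positive_features_errors(self):
        counts = np.array([[5, 0], [0, 7]])
        cm = OrfCountMatrix(["f", "g"], ["a", "b"], counts)
        with pytest.raises(ValueError):
            tmm_factors(cm)


class TestCpm:
    def test_basic_value(self):
        counts = np.zeros((2, 2), dtype=int)
        counts[0] = [100, 100]
        counts[1] = [10**6 - 100, 10**6 - 100]
        cm = OrfCountMatrix(["f", "g"], ["a", "b"], counts)
        vals = cpm(cm)
        assert vals[0, 0] == pytest.approx(100.0)

    def test_zero_count_is_zero(self):
        cm = OrfCountMatrix(["f", "g"], ["a", "b"], np.array([[0, 5], [10, 10]]))
        assert cpm(cm)[0, 0] == 0.0

    def test_scale_invariance_of_sample_doubling(self):
        """Doubling every count in one sample leaves CPM unchanged up to
        factor re-estimation: the residual is exactly the per-column ratio of
        re-estimated TMM factors (depth enters the trim weights)."""
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 300, size=(40, 3))
        cm1 = OrfCountMatrix([f"f{i}" for i in range(40)], list("abc"), counts)
        doubled = counts.copy()
        doubled[:, 1] *= 2
        cm2 = OrfCountMatrix([f"f{i}" for i in range(40)], list("abc"), doubled)
        v1, v2 = cpm(cm1), cpm(cm2)
        f1, f2 = cm1.tmm_factors, cm2.tmm_factors
        np.testing.assert_allclose(v2 * f2 / f1, v1, rtol=1e-9)
        # and the factor drift itself is small
        np.testing.assert_allclose(f1, f2, rtol=0.02)


class TestGrubbs:
    def test_clear_outlier_flagged(self):
        flags = grubbs_outliers([1, 1, 1, 10])
        assert flags.tolist() == [False, False, False, True]
        # G = 1.5 exceeds the closed-form critical value ≈ 1.481
        assert grubbs_critical(4, 0.05) == pytest.approx(1.481, abs=0.001)

    def test_no_outlier(self):
        assert not grubbs_outliers([1, 2, 3, 4]).any()

    def test_zero_variance_warns_empty(self):
        with pytest.warns(UserWarning):
            flags = grubbs_outliers([5, 5, 5])
        assert not flags.any()

    def test_too_small_sample_warns(self):
        with pytest.warns(UserWarning):
            flags = grubbs_outliers([1, 2])
        assert not flags.any()


class TestTE:
    def test_basic_ratio(self):
        te, excl = translation_efficiency([100], [50], 1000, 1000)
        assert te[0] == pytest.approx(2.0)
        assert not excl[0]

    def test_zero_rna_excluded(self):
        te, excl = translation_efficiency([100], [0], 1000, 1000)
        assert np.isnan(te[0]) and excl[0]

    def test_libsize_scale_invariance(self):
        te1, _ = translation_efficiency([100], [50], 1000, 2000)
        te2, _ = translation_efficiency([100], [50], 10_000, 20_000)
        assert te1[0] == pytest.approx(te2[0])


class TestDeltaTE:
    def test_log2fc_arithmetic(self):
        res = delta_te([100], [50], [25], [50], 1e4, 1e4, 1e4, 1e4)
        assert res.log2fc_te.iloc[0] == pytest.approx(-2.0)

    def test_identical_counts_null(self):
        res = delta_te([100], [50], [100], [50], 1e4, 1e4, 1e4, 1e4)
        assert res.log2fc_te.iloc[0] == 0.0
        assert res.p_value.iloc[0] == pytest.approx(1.0)

    def test_small_counts_match_exact_oracle(self):
        """For small tables the p-value equals the exact-test enumeration
        oracle (Fisher path, margins ≤ 12)."""
        for table in [([3, 2], [1, 5]), ([4, 1], [2, 4]), ([2, 2], [3, 3])]:
            (ra, na), (rb, nb) = table
            res = delta_te([ra], [na], [rb], [nb], 100, 100, 100, 100)
            expected = fisher_two_sided([[ra, na], [rb, nb]])
            assert res.p_value.iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_rna_zero_gives_excluded_status(self):
        res = delta_te([10], [0], [10], [5], 100, 100, 100, 100)
        assert res.status.iloc[0] == "excluded"
        assert np.isnan(res.p_value.iloc[0])

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(6)
        ra = rng.integers(10, 100, 20)
        na = rng.integers(10, 100, 20)
        rb = rng.integers(10, 100, 20)
        nb = rng.integers(10, 100, 20)
        res = delta_te(ra, na, rb, nb, 1e4, 1e4, 1e4, 1e4)
        tested = res[res.status == "tested"]
        assert (tested.adj_p >= tested.p_value - 1e-12).all()

    def test_parameter_recovery_planted_te_shift(self):
        """A planted 4× ribosome-loading increase is recovered as a median
        log2FC near 2 at adequate counts."""
        rng = np.random.default_rng(7)
        n = 200
        rna_mu = rng.uniform(50, 400, n)
        ra = rng.poisson(rna_mu)  # ribo A proportional to RNA
        na = rng.poisson(rna_mu)
        rb = rng.poisson(4 * rna_mu)  # 4x TE in B, RNA unchanged
        nb = rng.poisson(rna_mu)
        res = delta_te(
            ra, na, rb, nb,
            ra.sum(), na.sum(), rb.sum(), nb.sum(),
        )
        # library normalization absorbs part of a global shift; use raw totals
        res2 = delta_te(ra, na, rb, nb, 1e5, 1e5, 1e5, 1e5)
        med = np.nanmedian(res2.log2fc_te)
        assert 1.7 <= med <= 2.3
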