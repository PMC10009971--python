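"""Fragment-length summaries and the three classification features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ctfrag.background import VariantPartition
from ctfrag.features import (
    FragmentFeatureVector,
    bin_short_long_ratios,
    build_feature_matrix,
    contingency_table,
    feature1_short_long_fraction,
    feature2_size_enrichment,
    feature3_lambda_profile,
    filter_for_features,
    flen_distribution,
    matrix_from_table,
    restrict_lengths,
)
from ctfrag.io import read_feature_table, write_feature_table


def _frame(lengths):
    return pd.DataFrame(
        {
            "sample_id": "s",
            "variant_key": "chr1:1:A:T",
            "length": lengths,
            "allele": "REF",
        }
    )


class TestRestrictLengths:
    def test_boundaries_inclusive(self):
        out = restrict_lengths(_frame([99, 100, 250, 251]))
        assert sorted(out["length"]) == [100, 250]

    def test_empty_and_identity(self):
        assert len(restrict_lengths(_frame([]))) == 0
        out = restrict_lengths(_frame([150, 166]))
        assert sorted(out["length"]) == [150, 166]


class TestFlenDistribution:
    def test_single_size(self):
        d = flen_distribution(np.array([166] * 7))
        assert d.shape == (151,)
        assert d[166 - 100] == 100.0
        assert d.sum() == pytest.approx(100.0)

    def test_two_extremes(self):
        d = flen_distribution(np.array([100, 250]))
        assert d[0] == 50.0 and d[-1] == 50.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            flen_distribution(np.array([], dtype=int))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(100, 250), min_size=1, max_size=400))
    def test_normalization_property(self, lengths):
        d = flen_distribution(np.array(lengths))
        assert d.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(d >= 0)


class TestBinRatios:
    def test_single_bin_ratio(self):
        df = pd.DataFrame(
            {
                "sample_id": "s",
                "chrom": "chr1",
                "start": np.arange(15) * 1000,
                "length": [120] * 10 + [200] * 5,
            }
        )
        out = bin_short_long_ratios(df, {"chr1": 4_000_000})
        assert len(out) == 1
        assert out["ratio"].iloc[0] == pytest.approx(2.0)

    def test_zero_long_reads_flagged_missing(self):
        df = pd.DataFrame(
            {"sample_id": "s", "chrom": "chr1", "start": [0, 10], "length": [120, 130]}
        )
        out = bin_short_long_ratios(df, {"chr1": 1_000_000})
        assert np.isnan(out["ratio"].iloc[0])

    def test_bin_count_ceiling_convention(self):
        df = pd.DataFrame(
            {"sample_id": "s", "chrom": ["chr1", "chr2"], "start": [0, 0], "length": [120, 200]}
        )
        out = bin_short_long_ratios(df, {"chr1": 12_000_000, "chr2": 7_000_000})
        assert len(out) == 3 + 2  # ceil(12/5) + ceil(7/5)

    def test_sex_chromosome_fragments_dropped(self):
        df = pd.DataFrame(
            {"sample_id": "s", "chrom": ["chr1", "chrX"], "start": [0, 0], "length": [120, 120]}
        )
        out = bin_short_long_ratios(df, {"chr1": 5_000_000})
        assert set(out["chrom"]) == {"chr1"}

    def test_fragment_beyond_chromosome_errors(self):
        df = pd.DataFrame(
            {"sample_id": "s", "chrom": "chr1", "start": [6_000_000], "length": [120]}
        )
        with pytest.raises(ValueError, match="beyond"):
            bin_short_long_ratios(df, {"chr1": 5_000_000})


class TestFeature1:
    def test_forty_short_sixty_long(self):
        lengths = np.array([120] * 40 + [200] * 60)
        assert feature1_short_long_fraction(lengths) == pytest.approx(40 / 60)

    def test_boundary_150_is_short(self):
        assert feature1_short_long_fraction(np.array([150, 151])) == pytest.approx(1.0)

    def test_all_short_clamps_denominator(self):
        assert feature1_short_long_fraction(np.array([120] * 9)) == 9.0

    def test_no_alt_errors(self):
        with pytest.raises(ValueError, match="ALT"):
            feature1_short_long_fraction(np.array([]))


class TestFeature2:
    def test_balanced_table_no_enrichment_signal(self):
        # one-tailed test: a balanced table carries no enrichment evidence
        # (p = P(X >= 5) ~ 0.67 under the hypergeometric null)
        alt = np.array([120] * 5 + [200] * 5)
        ref = np.array([120] * 5 + [200] * 5)
        p = stats.hypergeom.sf(4, 20, 10, 10)
        assert feature2_size_enrichment(alt, ref) == pytest.approx(-10 * np.log10(p))
        # ALT depleted in the window: p ~ 1, PHRED ~ 0
        alt_dep = np.array([120] + [200] * 9)
        ref_en = np.array([120] * 9 + [200])
        assert feature2_size_enrichment(alt_dep, ref_en) < 0.1

    def test_phred_definition(self):
        # p = 0.001 exactly corresponds to PHRED 30
        assert -10 * np.log10(0.001) == pytest.approx(30.0)

    def test_contingency_margins(self):
        alt = np.array([120, 120, 200])
        ref = np.array([111, 205, 210, 240])
        a, b, c, d = contingency_table(alt, ref)
        assert (a + b, c + d) == (4, 3)
        assert (a, c) == (1, 2)

    def test_one_side_only_errors(self):
        with pytest.raises(ValueError):
            feature2_size_enrichment(np.array([120]), np.array([]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_hypergeometric_enumeration_oracle(self, a, b, c, d):
        """The one-tailed Fisher p equals the explicit hypergeometric tail
        over the 2x2 margins."""
        if a + b == 0 or c + d == 0:
            return
        # direct enumeration: P(X >= c) for X ~ Hypergeom(N, K=a+c, n=c+d)
        n_total = a + b + c + d
        in_window = a + c
        n_alt = c + d
        p_oracle = sum(
            stats.hypergeom.pmf(k, n_total, in_window, n_alt)
            for k in range(c, min(in_window, n_alt) + 1)
        )
        alt = np.array([120] * c + [200] * d)
        ref = np.array([120] * a + [200] * b)
        f2 = feature2_size_enrichment(alt, ref)
        expected = min(300.0, -10 * np.log10(max(p_oracle, 1e-300)))
        assert f2 == pytest.approx(expected, abs=1e-7)


class TestFeature3:
    def test_identical_distributions_give_flat_tens(self):
        lengths = np.concatenate([np.arange(100, 251), np.array([150] * 20)])
        f3 = feature3_lambda_profile(lengths, lengths.copy())
        assert f3.shape == (15,)
        np.testing.assert_allclose(f3, 10.0, atol=1e-12)

    def test_fifteen_windows_always(self, rng):
        alt = rng.integers(100, 251, 500)
        ref = rng.integers(100, 251, 500)
        assert feature3_lambda_profile(alt, ref).shape == (15,)

    def test_brute_force_elementwise_oracle(self):
        """Windowed sums match a direct per-size computation on a toy set
        with ALT concentrated at 145-149."""
        alt = np.array([145, 146, 147, 148, 149] * 4)
        ref = np.array([160, 165, 166, 170, 175] * 4)
        alt_counts = np.zeros(151)
        ref_counts = np.zeros(151)
        for x in alt:
            alt_counts[x - 100] += 1
        for x in ref:
            ref_counts[x - 100] += 1
        pa = (alt_counts + 1) / (alt_counts + 1).sum()
        pr = (ref_counts + 1) / (ref_counts + 1).sum()
        lam = pa / pr
        expected = np.array([lam[10 * k : 10 * k + 10].sum() for k in range(15)])
        np.testing.assert_allclose(feature3_lambda_profile(alt, ref), expected, atol=1e-12)

    def test_size_250_excluded(self):
        # fragments only at 250 bp influence no window
        alt = np.array([250] * 50 + [120])
        ref = np.array([250] * 50 + [120])
        f3 = feature3_lambda_profile(alt, ref)
        np.testing.assert_allclose(f3, 10.0, atol=1e-12)

    def test_missing_class_errors(self):
        with pytest.raises(ValueError):
            feature3_lambda_profile(np.array([], dtype=int), np.array([166]))


class TestFilterForFeatures:
    def _partition(self, vafs, unique=True):
        df = pd.DataFrame(
            {
                "sample_id": "s",
                "compartment": "plasma",
                "chrom": "chr1",
                "pos": np.arange(len(vafs)) + 1,
                "ref": "A",
                "alt": "T",
                "ad": 10,
                "dp": 100,
                "vaf": vafs,
                "pvalue": 0.001,
            }
        )
        empty = df.iloc[:0]
        if unique:
            return VariantPartition(df, empty, pd.Series(dtype=float))
        return VariantPartition(empty, df, pd.Series(dtype=float))

    def test_strict_ceiling(self):
        part = self._partition([0.05, 0.1, 0.5])
        assert len(filter_for_features(part, 0.1)) == 1

    def test_share_wbc_never_passes(self):
        part = self._partition([0.01, 0.02], unique=False)
        assert len(filter_for_features(part, 0.1)) == 0

    def test_all_below_ceiling_identity(self):
        part = self._partition([0.01, 0.02, 0.03])
        assert len(filter_for_features(part, 0.1)) == 3


class TestFeatureMatrix:
    def _vectors(self, n):
        rng = np.random.default_rng(1)
        return [
            FragmentFeatureVector(f"s{i}", 0.5, 10.0, rng.random(15), label="cancer")
            for i in range(n)
        ]

    def test_shape_and_order(self):
        mat = build_feature_matrix(self._vectors(4))
        assert mat.shape == (4, 19)  # sample_id + label + 17 features
        assert list(mat["sample_id"]) == ["s0", "s1", "s2", "s3"]
        X, y, ids = matrix_from_table(mat)
        assert X.shape == (4, 17)

    def test_round_trip_through_tsv(self, tmp_path):
        mat = build_feature_matrix(self._vectors(3))
        path = tmp_path / "features.tsv"
        write_feature_table(mat, path)
        back = read_feature_table(path)
        pd.testing.assert_frame_equal(back, mat)

    def test_f3_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="15"):
            FragmentFeatureVector("s", 0.5, 1.0, np.zeros(14))
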