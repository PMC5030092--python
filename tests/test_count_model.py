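"""Counting, filtering, normalization and the NB Wald test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import optimize, special, stats

from driptools.count_model import (
    ALPHA_MIN,
    CountMatrix,
    SampleMeta,
    bh_adjust,
    count_reads_to_fragments,
    estimate_dispersion,
    filter_low_coverage,
    nb_wald_test,
    rpkm,
    size_factors_total_mapped,
)
from driptools.genome_digest import FragmentInterval
from tests.conftest import make_matrix, nb_draw, two_group_matrix

FRAGS = [
    FragmentInterval("c", 0, 21, "c:0-21"),
    FragmentInterval("c", 21, 100, "c:21-100"),
]


class TestCounting:
    def test_no_reads_gives_zero_column(self):
        col = count_reads_to_fragments(pd.DataFrame(columns=["contig", "pos"]), FRAGS)
        assert col.tolist() == [0, 0]

    def test_reads_assigned_by_five_prime_start(self):
        reads = pd.DataFrame({"contig": ["c"] * 3, "pos": [5, 21, 22]})
        col = count_reads_to_fragments(reads, FRAGS)
        assert col.tolist() == [1, 2]

    def test_boundary_read_falls_in_downstream_fragment(self):
        col = count_reads_to_fragments(pd.DataFrame({"contig": ["c"], "pos": [21]}), FRAGS)
        assert col.tolist() == [0, 1]

    def test_minus_strand_reads_use_end_minus_one(self):
        reads = pd.DataFrame(
            {"contig": ["c"], "start": [10], "end": [22], "strand": ["-"]}
        )
        col = count_reads_to_fragments(reads, FRAGS)
        assert col.tolist() == [0, 1]  # 5' end at 21

    def test_off_contig_reads_dropped(self, caplog):
        reads = pd.DataFrame({"contig": ["c", "other"], "pos": [5, 5]})
        col = count_reads_to_fragments(reads, FRAGS)
        assert col.sum() == 1


class TestFilter:
    def test_hand_computed_keep_drop(self):
        m = make_matrix([[12, 15], [9, 30], [10, 10]])
        kept = filter_low_coverage(m, 10)
        assert list(kept.counts.index) == ["f0", "f2"]

    def test_min_count_zero_is_identity(self):
        m = make_matrix([[0, 5], [1, 2]])
        assert filter_low_coverage(m, 0).counts.equals(m.counts)

    def test_all_rows_removed_without_error(self):
        m = make_matrix([[1, 2], [3, 4]])
        assert len(filter_low_coverage(m, 10).counts) == 0

    def test_all_samples_mode(self):
        m = make_matrix([[12, 3], [4, 5]])
        assert list(filter_low_coverage(m, 10, mode="all").counts.index) == ["f0"]

    @settings(max_examples=50, deadline=None)
    @given(
        arrays(np.int64, (6, 3), elements=st.integers(0, 40)),
        st.integers(0, 30),
    )
    def test_idempotent(self, counts, min_count):
        m = make_matrix(counts)
        once = filter_low_coverage(m, min_count)
        twice = filter_low_coverage(once, min_count)
        assert once.counts.equals(twice.counts)


class TestSizeFactors:
    def test_equal_totals_give_unit_factors(self):
        m = make_matrix([[1, 1, 1]], totals=[5e6] * 3)
        assert np.allclose(size_factors_total_mapped(m.samples), 1.0)

    def test_two_sample_geometric_anchoring(self):
        m = make_matrix([[1, 1]], totals=[1_000_000, 2_000_000])
        np.testing.assert_allclose(
            size_factors_total_mapped(m.samples), [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_single_sample_factor_one(self):
        m = make_matrix([[1]], totals=[7_654_321])
        assert np.allclose(size_factors_total_mapped(m.samples), 1.0)

    def test_accepts_sample_meta_sequence(self):
        meta = [SampleMeta("a", "mock", "IP", 1, 10), SampleMeta("b", "mock", "IP", 2, 10)]
        assert np.allclose(size_factors_total_mapped(meta), 1.0)


class TestDispersion:
    def test_moment_formula(self):
        # moment formula (var - mean)/mean^2: mean 10, var 36 -> alpha 0.26
        m = make_matrix([[4, 10, 16]])
        sf = pd.Series(1.0, index=m.counts.columns)
        a = estimate_dispersion(m, {"g": list(m.counts.columns)}, sf)
        np.testing.assert_allclose(a.iloc[0], (36 - 10) / 100)

    def test_poisson_floor(self):
        m = make_matrix([[9, 10, 11]])  # var 1 <= mean 10
        sf = pd.Series(1.0, index=m.counts.columns)
        assert estimate_dispersion(m, {"g": list(m.counts.columns)}, sf).iloc[0] == ALPHA_MIN

    def test_all_zero_row_floors(self):
        m = make_matrix([[0, 0, 0]])
        sf = pd.Series(1.0, index=m.counts.columns)
        assert estimate_dispersion(m, {"g": list(m.counts.columns)}, sf).iloc[0] == ALPHA_MIN

    def test_needs_replicates(self):
        m = make_matrix([[5, 6]], conditions=["a", "b"])
        sf = pd.Series(1.0, index=m.counts.columns)
        with pytest.raises(ValueError, match=">= 2 samples"):
            estimate_dispersion(m, {"a": ["s0"], "b": ["s1"]}, sf)

    def test_recovery_with_many_replicates(self, rng):
        # NB(mean 50, alpha 0.1), 50 replicates per fragment
        n_frag, true_alpha = 1000, 0.1
        counts = nb_draw(rng, np.full((n_frag, 50), 50.0), true_alpha)
        m = make_matrix(counts)
        sf = pd.Series(1.0, index=m.counts.columns)
        a = estimate_dispersion(m, {"g": list(m.counts.columns)}, sf).to_numpy()
        within = np.abs(a - true_alpha) <= 0.5 * true_alpha
        assert within.mean() >= 0.9

    def test_pooled_method_single_value(self, rng):
        counts = nb_draw(rng, np.full((500, 6), 50.0), 0.05)
        m = make_matrix(counts)
        sf = pd.Series(1.0, index=m.counts.columns)
        a = estimate_dispersion(m, {"g": list(m.counts.columns)}, sf, method="pooled")
        assert a.nunique() == 1
        assert 0.02 <= a.iloc[0] <= 0.1


def nb_loglik(counts, mu, alpha):
    """NB log-likelihood in mean/dispersion form (size r = 1/alpha)."""
    r = 1.0 / alpha
    c = np.asarray(counts, dtype=float)
    return float(
        np.sum(
            special.gammaln(c + r)
            - special.gammaln(r)
            - special.gammaln(c + 1)
            + r * np.log(r / (r + mu))
            + c * np.log(mu / (r + mu))
        )
    )


def lrt_pvalue(ref_counts, alt_counts, alpha):
    """Numeric likelihood-ratio oracle for a single two-group fragment."""

    def fit(counts):
        res = optimize.minimize_scalar(
            lambda logmu: -nb_loglik(counts, np.exp(logmu), alpha),
            bounds=(-5, 15),
            method="bounded",
        )
        return -res.fun

    ll_full = fit(ref_counts) + fit(alt_counts)
    ll_red = fit(np.concatenate([ref_counts, alt_counts]))
    stat = max(2 * (ll_full - ll_red), 0.0)
    return stats.chi2.sf(stat, df=1)


class TestWaldTest:
    def test_identical_counts_give_null_result(self):
        m = make_matrix(
            [[30, 30, 30, 30, 30, 30]],
            conditions=["r"] * 3 + ["a"] * 3,
        )
        res = nb_wald_test(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"], dispersion=0.05)
        assert res["log2fc"].iloc[0] == 0.0
        assert res["pvalue"].iloc[0] == 1.0

    def test_planted_fourfold_enrichment_recovered(self, rng):
        n_frag = 2000
        m, ref, alt = two_group_matrix(
            rng, np.full(n_frag, 25.0), alpha=0.05, planted_idx=np.arange(n_frag),
            planted_log2fc=2.0,
        )
        res = nb_wald_test(m, ref, alt)
        assert 1.8 <= res["log2fc"].mean() <= 2.2

    def test_agrees_with_lrt_oracle(self, rng):
        alpha = 0.05
        cases = [
            (np.array([40, 55, 47]), np.array([60, 52, 70])),
            (np.array([20, 25, 22]), np.array([90, 110, 85])),
            (np.array([100, 90, 120]), np.array([95, 105, 100])),
            (np.array([12, 18, 15]), np.array([15, 11, 19])),
        ]
        for ref_counts, alt_counts in cases:
            m = make_matrix(
                np.concatenate([ref_counts, alt_counts])[None, :],
                conditions=["r"] * 3 + ["a"] * 3,
            )
            res = nb_wald_test(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"], dispersion=alpha)
            p_lrt = lrt_pvalue(ref_counts, alt_counts, alpha)
            assert abs(res["pvalue"].iloc[0] - p_lrt) < 0.05

    def test_zero_reference_group_stays_finite(self):
        m = make_matrix([[0, 0, 0, 20, 25, 30]], conditions=["r"] * 3 + ["a"] * 3)
        res = nb_wald_test(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"], dispersion=0.05)
        assert np.isfinite(res["log2fc"].iloc[0])
        assert res["log2fc"].iloc[0] > 4

    def test_empty_group_rejected(self):
        m = make_matrix([[1, 2]], conditions=["r", "a"])
        with pytest.raises(ValueError, match="non-empty"):
            nb_wald_test(m, [], ["s0", "s1"])

    def test_normalization_invariance(self, rng):
        """Scaling one sample's counts and total together changes nothing."""
        counts = nb_draw(rng, np.full((200, 6), 50.0), 0.05)
        totals = [1e6] * 6
        m1 = make_matrix(counts, totals=totals, conditions=["r"] * 3 + ["a"] * 3)
        k = 3
        counts2 = counts.copy()
        counts2[:, 0] *= k
        totals2 = list(totals)
        totals2[0] *= k
        m2 = make_matrix(counts2, totals=totals2, conditions=["r"] * 3 + ["a"] * 3)
        r1 = nb_wald_test(m1, ["s0", "s1", "s2"], ["s3", "s4", "s5"], dispersion=0.05)
        r2 = nb_wald_test(m2, ["s0", "s1", "s2"], ["s3", "s4", "s5"], dispersion=0.05)
        for col in ("log2fc", "se", "pvalue"):
            np.testing.assert_allclose(r1[col], r2[col], atol=1e-9)


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_without_entering_ranking(self):
        adj = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], bh_adjust([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(pvals), expected, atol=1e-12)


class TestRpkm:
    def test_forced_by_formula(self):
        counts = pd.DataFrame({"s": [10]}, index=["f"])
        out = rpkm(counts, np.array([1000.0]), {"s": 1_000_000})
        np.testing.assert_allclose(out["s"], [10.0])

    def test_zero_count_zero_rpkm(self):
        counts = pd.DataFrame({"s": [0]}, index=["f"])
        assert rpkm(counts, np.array([500.0]), {"s": 1e6})["s"].iloc[0] == 0.0

    def test_doubling_total_halves_rpkm(self):
        counts = pd.DataFrame({"s": [10]}, index=["f"])
        a = rpkm(counts, np.array([1000.0]), {"s": 1e6})["s"].iloc[0]
        b = rpkm(counts, np.array([1000.0]), {"s": 2e6})["s"].iloc[0]
        assert b == a / 2

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            rpkm(pd.DataFrame({"s": [1]}), np.array([0.0]), {"s": 1e6})


class TestCountMatrixInvariants:
    def test_duplicate_sample_key_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_matrix([[1, 2]], conditions=["a", "a"], assays=["IP", "IP"],
                        replicates=[1, 1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_matrix([[-1, 2]])
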