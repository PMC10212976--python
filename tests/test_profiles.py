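"""Counting, pseudocounts, normalisation, Blackman smoothing, replicate
aggregation and read classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribopause import (
    PositionProfile,
    ReadRecord,
    TranscriptionUnit,
    add_pseudocounts,
    aggregate_replicates,
    blackman_smooth,
    classify_reads,
    count_three_prime_ends,
    smooth_blackman,
    to_fractions,
)
from ribopause.profiles import ProfileError


def profile(values, kind="count", **meta):
    return PositionProfile(np.asarray(values, dtype=float), kind, meta)


class TestCounting:
    def test_no_reads_gives_zero_vector(self, tiny_unit):
        counts = count_three_prime_ends([], tiny_unit)
        assert np.array_equal(counts.values, np.zeros(10))

    def test_tally_by_three_prime_end(self, tiny_unit):
        reads = [
            ReadRecord("chrT", 2, 6, "+"),
            ReadRecord("chrT", 0, 6, "+"),
            ReadRecord("chrT", 5, 10, "+"),
        ]
        counts = count_three_prime_ends(reads, tiny_unit)
        assert np.array_equal(counts.values, [0, 0, 0, 0, 0, 2, 0, 0, 0, 1])
        assert counts.values.sum() == 3

    def test_fractional_weights_sum(self, tiny_unit):
        reads = [ReadRecord("chrT", 0, 6, "+", weight=0.25) for _ in range(4)]
        counts = count_three_prime_ends(reads, tiny_unit)
        assert counts.values[5] == pytest.approx(1.0)

    def test_mass_conservation_with_out_of_unit_reads(self, tiny_unit):
        reads = [
            ReadRecord("chrT", 0, 6, "+"),
            ReadRecord("chrT", 50, 60, "+"),   # outside
            ReadRecord("chrT", 0, 6, "-"),     # wrong strand
            ReadRecord("chrX", 0, 6, "+"),     # wrong chrom
        ]
        counts = count_three_prime_ends(reads, tiny_unit)
        assert counts.values.sum() == 1.0


class TestNormalisation:
    def test_zero_pseudocount_is_identity(self):
        p = profile([0, 3])
        assert np.array_equal(add_pseudocounts(p, 0.0).values, [0, 3])

    def test_pseudocount_addition_recorded(self):
        p = add_pseudocounts(profile([0, 3]), 1.0)
        assert np.array_equal(p.values, [1, 4])
        assert p.meta["pseudocount"] == 1.0

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ProfileError):
            add_pseudocounts(profile([1, 2]), -0.5)

    def test_fractions_from_pseudocounted_counts(self):
        fractions = to_fractions(add_pseudocounts(profile([0, 3]), 1.0))
        assert np.allclose(fractions.values, [0.2, 0.8])
        assert fractions.kind == "fraction"

    def test_all_zero_counts_error_mentions_pseudocounts(self):
        with pytest.raises(ProfileError, match="pseudocount"):
            to_fractions(profile([0, 0, 0]))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=50))
    def test_fractions_scale_invariant_and_normalised(self, counts):
        counts = np.asarray(counts, dtype=float) + 1.0
        f1 = to_fractions(profile(counts)).values
        f2 = to_fractions(profile(counts * 10)).values
        assert np.allclose(f1, f2)
        assert f1.sum() == pytest.approx(1.0, abs=1e-12)


class TestBlackmanSmoothing:
    def test_constant_profile_is_fixed_point(self):
        values = np.full(200, 0.005)
        assert np.allclose(blackman_smooth(values, 31), 0.005, atol=1e-12)

    def test_impulse_response_window5_closed_form(self):
        out = blackman_smooth(np.array([0, 0, 1.0, 0, 0]), 5)
        expected = [0.0, 0.202381, 0.595238, 0.202381, 0.0]
        assert np.allclose(out, expected, atol=1e-6)

    def test_interior_impulse_mass_is_conserved(self):
        values = np.zeros(101)
        values[50] = 1.0
        assert blackman_smooth(values, 31).sum() == pytest.approx(1.0, abs=1e-12)

    def test_even_window_adjusted_to_odd(self):
        p = profile(np.full(100, 0.01), kind="fraction")
        smoothed = smooth_blackman(p, 30)
        assert smoothed.meta["window"] == 31  # effective odd window recorded
        assert np.allclose(smoothed.values, 0.01)

    def test_window_larger_than_profile_rejected(self):
        with pytest.raises(ProfileError, match="window"):
            blackman_smooth(np.ones(10), 31)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(80), rng.random(80)
        lhs = blackman_smooth(2 * a + 3 * b, 11)
        rhs = 2 * blackman_smooth(a, 11) + 3 * blackman_smooth(b, 11)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_smoothed_fraction_keeps_unit_sum(self):
        rng = np.random.default_rng(1)
        raw = rng.random(500)
        p = profile(raw / raw.sum(), kind="fraction")
        assert smooth_blackman(p, 51).values.sum() == pytest.approx(1.0, abs=1e-12)


class TestAggregation:
    def test_identical_replicates_zero_band(self):
        p = profile(np.linspace(0.1, 0.9, 5))
        agg = aggregate_replicates([p, p])
        assert np.array_equal(agg.median, p.values)
        assert np.array_equal(agg.band_low, agg.band_high)

    def test_two_replicates_median_and_quartiles(self):
        agg = aggregate_replicates([profile([0.2]), profile([0.4])])
        assert agg.median[0] == pytest.approx(0.3)
        assert agg.band_low[0] == pytest.approx(0.3)
        assert agg.band_high[0] == pytest.approx(0.35)

    def test_permutation_invariance_and_band_order(self):
        rng = np.random.default_rng(2)
        replicates = [profile(rng.random(40)) for _ in range(4)]
        a = aggregate_replicates(replicates)
        b = aggregate_replicates(replicates[::-1])
        assert np.array_equal(a.median, b.median)
        assert np.all(a.band_low <= a.median + 1e-12)
        assert np.all(a.median <= a.band_high + 1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ProfileError, match="length"):
            aggregate_replicates([profile([1, 2]), profile([1, 2, 3])])


class TestClassifyReads:
    categories = {
        "rRNA": [("chr3", 0, 1000)],
        "mRNA": [("chr1", 0, 500), ("chr2", 0, 500)],
    }

    def test_all_reads_in_one_category(self):
        reads = [ReadRecord("chr3", i, i + 50, "+") for i in range(0, 500, 100)]
        fractions = classify_reads(reads, self.categories)
        assert fractions["rRNA"] == pytest.approx(1.0)

    def test_three_to_one_split(self):
        reads = [
            ReadRecord("chr3", 0, 50, "+"),
            ReadRecord("chr3", 100, 150, "+"),
            ReadRecord("chr3", 200, 250, "+"),
            ReadRecord("chr1", 0, 50, "+"),
        ]
        fractions = classify_reads(reads, self.categories)
        assert fractions["rRNA"] == pytest.approx(0.75)
        assert fractions["mRNA"] == pytest.approx(0.25)

    def test_unassigned_and_total(self):
        reads = [
            ReadRecord("chr3", 0, 50, "+"),
            ReadRecord("chr9", 0, 50, "+"),
        ]
        fractions = classify_reads(reads, self.categories)
        assert fractions["unassigned"] == pytest.approx(0.5)
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_tie_goes_to_earlier_priority(self):
        categories = {"A": [("chr1", 0, 100)], "B": [("chr1", 0, 100)]}
        fractions = classify_reads(
            [ReadRecord("chr1", 10, 20, "+")], categories, priority=["B", "A"]
        )
        assert fractions["B"] == pytest.approx(1.0)

    def test_empty_read_set_rejected(self):
        with pytest.raises(ProfileError):
            classify_reads([], self.categories)
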