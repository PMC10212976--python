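"""Occupancy-time conversion, log2 ratio tracks, pause calling, region
summaries, condition comparison and list intersection."""

import numpy as np
import pandas as pd
import pytest

from ribopause import (
    OccupancyParameters,
    PositionProfile,
    build_dwell_profile,
    compare_conditions,
    detect_pauses,
    expected_fractions,
    intersect_id_lists,
    load_builtin_unit,
    log2_ratio,
    occupancy_time,
    region_summary,
    simulate_condition_pair,
    simulate_reads,
    smooth_blackman,
)
from ribopause.compare import CompareError
from ribopause.io import read_bedgraph
from ribopause.profiles import blackman_smooth


def fraction_profile(values, **meta):
    values = np.asarray(values, dtype=float)
    return PositionProfile(values / values.sum(), "fraction", meta)


class TestOccupancyTime:
    def test_canonical_total_time(self):
        params = OccupancyParameters(unit_length=7800, velocity=40.0)
        assert params.t_total == pytest.approx(195.0)

    def test_uniform_profile_gives_25ms_everywhere(self):
        params = OccupancyParameters(unit_length=7800, velocity=40.0)
        uniform = fraction_profile(np.ones(7800))
        occupancy = occupancy_time(uniform, params)
        assert np.allclose(occupancy.values, 0.025)

    def test_one_per_mille_fraction_gives_195ms(self):
        params = OccupancyParameters(unit_length=7800, velocity=40.0)
        values = np.full(7800, (1 - 0.001) / 7799)
        values[100] = 0.001
        occupancy = occupancy_time(PositionProfile(values, "fraction"), params)
        assert occupancy.values[100] == pytest.approx(0.195)

    def test_total_time_conserved_for_any_fractions(self):
        rng = np.random.default_rng(0)
        params = OccupancyParameters(unit_length=500, velocity=40.0)
        profile = fraction_profile(rng.random(500))
        occupancy = occupancy_time(profile, params)
        assert occupancy.values.sum() == pytest.approx(params.t_total, abs=1e-9)

    def test_invalid_velocity_rejected(self):
        with pytest.raises(CompareError):
            OccupancyParameters(velocity=0.0)


class TestLog2Ratio:
    def test_identical_profiles_zero(self):
        p = fraction_profile(np.arange(1, 101))
        delta = log2_ratio(p, p, window=31)
        assert np.allclose(delta.values, 0.0, atol=1e-12)

    def test_unsmoothed_toy_example(self):
        test = fraction_profile([0.25, 0.75])
        ref = fraction_profile([0.5, 0.5])
        delta = log2_ratio(test, ref, window=None)
        assert np.allclose(delta.values, [-1.0, 0.584963], atol=1e-6)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = fraction_profile(rng.random(300) + 0.1)
        b = fraction_profile(rng.random(300) + 0.1)
        forward = log2_ratio(a, b, window=51).values
        backward = log2_ratio(b, a, window=51).values
        assert np.allclose(forward, -backward, atol=1e-12)


class TestDetectPauses:
    def test_constant_profile_has_no_pauses(self):
        p = fraction_profile(np.ones(200))
        assert detect_pauses(p) == []

    def test_single_smoothed_impulse_called_once(self):
        values = np.full(301, 1.0)
        values[150] = 50.0
        smoothed = smooth_blackman(fraction_profile(values), 5)
        sites = detect_pauses(smoothed)
        assert len(sites) == 1
        assert sites[0].position == 150
        assert sites[0].width >= 1

    def test_plateau_reports_leftmost_sample(self):
        values = np.ones(100)
        values[40:44] = 10.0
        sites = detect_pauses(PositionProfile(values, "count"), min_prominence=3.0)
        assert [s.position for s in sites] == [40]

    def test_recovers_well_separated_simulated_pauses(self, rdna_unit):
        positions = [1000, 2500, 4000, 5500, 7000]
        model = build_dwell_profile(7800, 0.025, positions, [10.0] * 5)
        reads = simulate_reads(model, rdna_unit, 5 * 10**5, seed=9)
        from ribopause import add_pseudocounts, count_three_prime_ends, to_fractions

        fractions = to_fractions(
            add_pseudocounts(count_three_prime_ends(reads, rdna_unit), 1.0)
        )
        sites = detect_pauses(smooth_blackman(fractions, 5))
        assert len(sites) == 5
        for site, truth in zip(sites, positions):
            assert abs(site.position - truth) <= 2


class TestRegionSummary:
    def test_uniform_fraction_region_sums(self, rdna_unit):
        uniform = fraction_profile(np.ones(7800))
        table = region_summary(uniform, rdna_unit).set_index("region")
        assert table.loc["5ETS", "sum"] == pytest.approx(1300 / 7800)
        assert table.loc["5ETS", "sum"] == pytest.approx(1 / 6)
        assert table["sum"].sum() == pytest.approx(1.0)

    def test_region_sums_additive_under_concatenation(self, tiny_unit):
        p = fraction_profile(np.arange(1, 11))
        table = region_summary(p, tiny_unit).set_index("region")
        assert table.loc["left", "sum"] + table.loc["right", "sum"] == pytest.approx(
            p.values.sum()
        )


class TestIntersectIdLists:
    def test_disjoint_lists(self):
        result = intersect_id_lists(["a", "b"], ["c", "d"])
        assert result["n_common"] == 0

    def test_case_normalised_intersection(self):
        result = intersect_id_lists(["p1", "p2", "p3"], ["P2", "p4"])
        assert result["intersection"] == ["p2"]
        assert (result["n_a"], result["n_b"], result["n_common"]) == (3, 2, 1)

    def test_identical_lists(self):
        result = intersect_id_lists(["x", "y", "z"], ["x", "y", "z"])
        assert result["n_common"] == result["n_a"] == 3


@pytest.fixture(scope="module")
def report(rdna_unit):
    positions = [1000, 2500, 4000, 5500, 7000]
    model = build_dwell_profile(7800, 0.025, positions, [10.0] * 5)
    dataset = simulate_condition_pair(
        model, 0.5, n_replicates=2, n_reads=10**5, seed=21, unit=rdna_unit
    )
    return compare_conditions(dataset.reads_by_sample, rdna_unit), model, dataset


class TestCompareConditions:

    def test_negative_delta_log2_at_true_pauses(self, report):
        result, model, _ = report
        assert np.all(result.delta_log2.values[list(model.pause_positions)] < 0)

    def test_occupancy_tracks_sum_to_t_total(self, report):
        result, _, _ = report
        for condition in ("wildtype", "depleted"):
            assert result.occupancy[condition].values.sum() == pytest.approx(195.0)

    def test_matched_table_has_one_row_per_reference_pause(self, report):
        result, model, _ = report
        matched = result.matched_pauses
        assert len(matched) == len(result.pauses["wildtype"])
        assert set(matched["position_ref"]) == set(model.pause_positions)

    def test_pause_matching_by_nearest_position_within_tolerance(self):
        from ribopause.compare import _match_pauses

        ref = pd.DataFrame({"position": [100, 500, 900], "score": [1.0, 2.0, 3.0]})
        test = pd.DataFrame({"position": [110, 880], "score": [0.5, 1.5]})
        matched = _match_pauses(ref, test, tolerance=50)
        assert matched["position_test"].tolist() == [110, pd.NA, 880]

    def test_report_round_trips_through_disk(self, report, rdna_unit, tmp_path):
        result, _, _ = report
        outdir = result.write(tmp_path / "report")
        delta = read_bedgraph(outdir / "delta_log2.bedgraph", rdna_unit)
        assert np.array_equal(delta, result.delta_log2.values)
        pauses = pd.read_csv(outdir / "pauses_wildtype.tsv", sep="\t")
        assert pauses["position"].tolist() == result.pauses["wildtype"]["position"].tolist()

    def test_missing_condition_rejected(self, rdna_unit):
        model = build_dwell_profile(7800, 0.025)
        reads = simulate_reads(model, rdna_unit, 100, seed=0)
        with pytest.raises(CompareError, match="depleted"):
            compare_conditions({("wildtype", 1): reads, ("wildtype", 2): reads}, rdna_unit)

    def test_no_depletion_gives_small_mean_abs_delta(self, rdna_unit):
        model = build_dwell_profile(7800, 0.025, [2000, 5000], [10.0, 10.0])
        dataset = simulate_condition_pair(
            model, 1.0, n_replicates=2, n_reads=2 * 10**5, seed=33, unit=rdna_unit
        )
        result = compare_conditions(dataset.reads_by_sample, rdna_unit)
        assert np.mean(np.abs(result.delta_log2.values)) < 0.1
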