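"""Condition comparison and kinetic interpretation.

Log2 ratio tracks between depleted and reference conditions, conversion of
read fractions into polymerase occupancy times, pause-site calling on
smoothed tracks, per-region summaries, and protein-list intersection.

The occupancy-time conversion assumes independent polymerases: with total
transit time T_total = unit_length / mean velocity, the average dwell at
position i is t_i = f_i * T_total where f_i is the fraction of read 3'
ends at i. With the canonical 7800-nt rDNA unit and 40 nt/s mean RNAPI
velocity, T_total = 195 s and a uniform profile gives 25 ms per position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ribopause.io import ReadRecord, TranscriptionUnit, write_track
from ribopause.profiles import (
    DEFAULT_PROFILE_WINDOW,
    DEFAULT_RATIO_WINDOW,
    AggregateProfile,
    PositionProfile,
    ProfileError,
    add_pseudocounts,
    aggregate_replicates,
    blackman_smooth,
    count_three_prime_ends,
    smooth_blackman,
    to_fractions,
)

#: Narrow smoothing window used for pause calling. A wide display window
#: attenuates a single-nucleotide pause of multiplier m to an elevation of
#: (m-1) * w0 / sum(w) above baseline (~0.7x for a 31-nt Blackman kernel at
#: m=10), below any robust prominence threshold; a 5-nt kernel keeps ~5.4x.
DEFAULT_PAUSE_WINDOW = 5
DEFAULT_MIN_DISTANCE = 50


class CompareError(ValueError):
    """Raised for invalid comparison inputs."""


@dataclass(frozen=True)
class OccupancyParameters:
    """Constants for the fraction -> occupancy-time conversion."""

    unit_length: int = 7800
    velocity: float = 40.0

    def __post_init__(self) -> None:
        if self.unit_length <= 0:
            raise CompareError("unit_length must be positive")
        if self.velocity <= 0:
            raise CompareError("velocity must be positive")

    @property
    def t_total(self) -> float:
        """Total transit time (seconds) = unit_length / velocity."""
        return self.unit_length / self.velocity


@dataclass(frozen=True)
class PauseSite:
    """A called pause: a local occupancy maximum on a smoothed track."""

    position: int
    score: float
    prominence: float
    width: float

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise CompareError("pause score must be positive")
        if self.width < 1:
            raise CompareError("pause width must be >= 1 nt")


# ---------------------------------------------------------------------------
# core operations


def occupancy_time(
    profile: PositionProfile, params: OccupancyParameters
) -> PositionProfile:
    """Convert a fraction profile into per-position occupancy times.

    t_i = f_i * T_total; the track conserves total time (sums to T_total).
    """
    if profile.kind not in ("fraction", "smoothed_fraction"):
        raise CompareError(
            f"occupancy_time expects a fraction profile, got {profile.kind}"
        )
    if len(profile) != params.unit_length:
        raise CompareError(
            f"profile length {len(profile)} != params unit_length {params.unit_length}"
        )
    return profile.with_values(
        profile.values * params.t_total,
        kind="occupancy_time_seconds",
        velocity=params.velocity,
        t_total=params.t_total,
    )


def log2_ratio(
    profile_test: PositionProfile,
    profile_ref: PositionProfile,
    window: int | None = DEFAULT_RATIO_WINDOW,
) -> PositionProfile:
    """log2 of the smoothed test/reference fraction ratio.

    Each input is Blackman-smoothed with the stated window before division
    (window None or 1 skips smoothing, for toy checks). Strict positivity
    is required and is guaranteed when pseudocounts were applied upstream.
    """
    if len(profile_test) != len(profile_ref):
        raise CompareError("profiles must have equal length")
    for p in (profile_test, profile_ref):
        if p.kind not in ("fraction", "smoothed_fraction"):
            raise CompareError(f"log2_ratio expects fraction profiles, got {p.kind}")
    if window is not None and window > 1:
        test = smooth_blackman(profile_test, window).values
        ref = smooth_blackman(profile_ref, window).values
    else:
        test, ref = profile_test.values, profile_ref.values
    if np.any(test <= 0) or np.any(ref <= 0):
        raise CompareError(
            "nonpositive smoothed fraction encountered; apply a pseudocount "
            "before computing log2 ratios"
        )
    meta = {
        "window": window,
        "test": profile_test.meta.get("condition"),
        "ref": profile_ref.meta.get("condition"),
    }
    return PositionProfile(np.log2(test / ref), "log2_ratio", meta)


def detect_pauses(
    profile: PositionProfile,
    min_prominence: float | None = None,
    min_distance: int = DEFAULT_MIN_DISTANCE,
) -> list[PauseSite]:
    """Call pause sites as prominent local maxima on a smoothed track.

    min_prominence defaults to 3x the median profile value. Peaks closer
    than min_distance keep only the more prominent one; the leftmost sample
    of a plateau is reported. Width is the extent above half prominence
    (floored at 1 nt).
    """
    values = profile.values
    if min_prominence is None:
        min_prominence = 3.0 * float(np.median(values))
    if min_prominence <= 0:
        raise CompareError("min_prominence must be positive")
    peaks, props = find_peaks(
        values,
        prominence=min_prominence,
        distance=max(int(min_distance), 1),
        width=1e-9,
        rel_height=0.5,
        plateau_size=1,
    )
    positions = props.get("left_edges", peaks)  # leftmost sample of plateaus
    sites = [
        PauseSite(
            position=int(pos),
            score=float(values[peak]),
            prominence=float(prom),
            width=max(float(width), 1.0),
        )
        for pos, peak, prom, width in zip(
            positions, peaks, props["prominences"], props["widths"]
        )
    ]
    sites.sort(key=lambda s: s.position)
    return sites


def pause_table(sites: Sequence[PauseSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": s.position,
                "score": s.score,
                "prominence": s.prominence,
                "width": s.width,
            }
            for s in sites
        ],
        columns=["position", "score", "prominence", "width"],
    )


def region_summary(
    profile: PositionProfile, unit: TranscriptionUnit
) -> pd.DataFrame:
    """Summed and mean signal per named unit region.

    An "outside_regions" row carries whatever signal the named regions do
    not cover, so for fraction profiles the sum column totals 1.
    """
    if len(profile) != unit.length:
        raise CompareError(
            f"profile length {len(profile)} != unit length {unit.length}"
        )
    rows = []
    covered = np.zeros(unit.length, dtype=bool)
    for region in unit.regions:
        chunk = profile.values[region.start:region.end]
        covered[region.start:region.end] = True
        rows.append(
            {
                "region": region.name,
                "start": region.start,
                "end": region.end,
                "length": region.length,
                "sum": float(chunk.sum()),
                "mean": float(chunk.mean()),
            }
        )
    outside = ~covered
    n_outside = int(outside.sum())
    rows.append(
        {
            "region": "outside_regions",
            "start": -1,
            "end": -1,
            "length": n_outside,
            "sum": float(profile.values[outside].sum()),
            "mean": float(profile.values[outside].mean()) if n_outside else 0.0,
        }
    )
    return pd.DataFrame(rows)


def intersect_id_lists(
    list_a: Iterable[str],
    list_b: Iterable[str],
    normalizer: Callable[[str], str] | None = None,
) -> dict:
    """Case-normalised, deduplicated intersection of two identifier lists.

    Returns the sorted intersection plus |A|, |B| and |A & B| after
    normalisation (default: strip whitespace and casefold).
    """
    if normalizer is None:
        normalizer = lambda s: s.strip().casefold()
    set_a = {normalizer(str(x)) for x in list_a}
    set_b = {normalizer(str(x)) for x in list_b}
    if not set_a or not set_b:
        raise CompareError("identifier lists must be nonempty")
    common = set_a & set_b
    return {
        "intersection": sorted(common),
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_common": len(common),
    }


# ---------------------------------------------------------------------------
# condition comparison report


@dataclass
class ComparisonReport:
    """Bundled output of a two-condition comparison."""

    unit: TranscriptionUnit
    params: OccupancyParameters
    condition_test: str
    condition_ref: str
    aggregates: dict[str, AggregateProfile]
    fractions: dict[str, PositionProfile]
    occupancy: dict[str, PositionProfile]
    delta_log2: PositionProfile
    pauses: dict[str, pd.DataFrame]
    matched_pauses: pd.DataFrame
    regions: pd.DataFrame
    settings: dict

    def write(self, outdir: str | Path) -> Path:
        """Write bedGraph tracks, TSV tables and a JSON run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for condition in sorted(self.aggregates):
            write_track(
                self.aggregates[condition].median,
                self.unit,
                outdir / f"profile_median_{condition}.bedgraph",
            )
            write_track(
                self.occupancy[condition].values,
                self.unit,
                outdir / f"occupancy_time_{condition}.bedgraph",
            )
            self.pauses[condition].to_csv(
                outdir / f"pauses_{condition}.tsv", sep="\t", index=False
            )
        write_track(self.delta_log2.values, self.unit, outdir / "delta_log2.bedgraph")
        self.matched_pauses.to_csv(outdir / "pauses_matched.tsv", sep="\t", index=False)
        self.regions.to_csv(outdir / "region_summary.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as handle:
            json.dump(self.settings, handle, indent=2, sort_keys=True)
        return outdir


def _match_pauses(
    pauses_ref: pd.DataFrame, pauses_test: pd.DataFrame, tolerance: int
) -> pd.DataFrame:
    """Match test pauses to reference pauses by nearest position within
    the given tolerance (the pause-caller min_distance by default)."""
    rows = []
    test_positions = pauses_test["position"].to_numpy()
    for _, ref in pauses_ref.iterrows():
        row = {
            "position_ref": int(ref["position"]),
            "score_ref": ref["score"],
            "position_test": pd.NA,
            "score_test": pd.NA,
        }
        if len(test_positions):
            offsets = np.abs(test_positions - ref["position"])
            j = int(np.argmin(offsets))
            if offsets[j] <= tolerance:
                row["position_test"] = int(test_positions[j])
                row["score_test"] = pauses_test["score"].iloc[j]
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["position_ref", "score_ref", "position_test", "score_test"]
    )


def replicate_fraction_profiles(
    reads_by_sample: Mapping[tuple[str, int], Sequence[ReadRecord]],
    unit: TranscriptionUnit,
    alpha: float = 1.0,
) -> dict[str, list[PositionProfile]]:
    """Counts -> pseudocounted fractions for every (condition, replicate)."""
    by_condition: dict[str, list[PositionProfile]] = {}
    for (condition, replicate), reads in sorted(reads_by_sample.items()):
        counts = count_three_prime_ends(reads, unit)
        fractions = to_fractions(add_pseudocounts(counts, alpha))
        fractions = fractions.with_values(
            fractions.values, condition=condition, replicate=replicate
        )
        by_condition.setdefault(condition, []).append(fractions)
    return by_condition


def _median_fraction(profiles: Sequence[PositionProfile], window: int) -> PositionProfile:
    """Smooth each replicate, take the per-position median, renormalise."""
    smoothed = [smooth_blackman(p, window) for p in profiles]
    if len(smoothed) == 1:
        values = smoothed[0].values
    else:
        values = aggregate_replicates(smoothed).median
    values = values / values.sum()
    meta = dict(smoothed[0].meta)
    meta.pop("replicate", None)
    return PositionProfile(values, "smoothed_fraction", meta)


def compare_conditions(
    reads_by_sample: Mapping[tuple[str, int], Sequence[ReadRecord]],
    unit: TranscriptionUnit,
    params: OccupancyParameters | None = None,
    condition_test: str = "depleted",
    condition_ref: str = "wildtype",
    alpha: float = 1.0,
    profile_window: int = DEFAULT_PROFILE_WINDOW,
    ratio_window: int = DEFAULT_RATIO_WINDOW,
    pause_window: int = DEFAULT_PAUSE_WINDOW,
    min_prominence: float | None = None,
    min_distance: int = DEFAULT_MIN_DISTANCE,
) -> ComparisonReport:
    """Full two-condition comparison.

    Per replicate: count 3' ends, add the pseudocount, normalise to
    fractions. Per condition: smooth each replicate with profile_window and
    aggregate as median + quartile band; a narrower pause_window smoothing
    feeds the pause caller; a ratio_window smoothing of the replicate
    medians feeds the log2 ratio (test over reference). Occupancy times use
    the profile_window median renormalised to unit sum.
    """
    params = params or OccupancyParameters(unit_length=unit.length)
    if params.unit_length != unit.length:
        raise CompareError(
            f"params.unit_length {params.unit_length} != unit length {unit.length}"
        )
    by_condition = replicate_fraction_profiles(reads_by_sample, unit, alpha)
    for condition in (condition_test, condition_ref):
        if condition not in by_condition:
            raise CompareError(f"no samples for condition {condition!r}")

    aggregates: dict[str, AggregateProfile] = {}
    display: dict[str, PositionProfile] = {}
    ratio_input: dict[str, PositionProfile] = {}
    occupancy: dict[str, PositionProfile] = {}
    pauses: dict[str, pd.DataFrame] = {}
    region_frames = []
    for condition, replicates in sorted(by_condition.items()):
        smoothed = [smooth_blackman(p, profile_window) for p in replicates]
        aggregates[condition] = (
            aggregate_replicates(smoothed)
            if len(smoothed) > 1
            else AggregateProfile(
                smoothed[0].values, smoothed[0].values, smoothed[0].values,
                1, smoothed[0].kind, dict(smoothed[0].meta),
            )
        )
        display[condition] = _median_fraction(replicates, profile_window)
        ratio_input[condition] = _median_fraction(replicates, ratio_window)
        occupancy[condition] = occupancy_time(display[condition], params)
        pause_profile = _median_fraction(replicates, pause_window)
        pauses[condition] = pause_table(
            detect_pauses(pause_profile, min_prominence, min_distance)
        )
        frame = region_summary(display[condition], unit)
        frame.insert(0, "condition", condition)
        region_frames.append(frame)

    delta = log2_ratio(ratio_input[condition_test], ratio_input[condition_ref], window=None)
    delta = delta.with_values(
        delta.values, test=condition_test, ref=condition_ref, window=ratio_window
    )
    regions = pd.concat(region_frames, ignore_index=True)
    deltas = (
        regions.pivot(index="region", columns="condition", values="sum")
        .reset_index()
    )
    if condition_test in deltas and condition_ref in deltas:
        deltas["delta_fraction"] = deltas[condition_test] - deltas[condition_ref]
        regions = regions.merge(deltas[["region", "delta_fraction"]], on="region")

    settings = {
        "alpha": alpha,
        "profile_window": int(profile_window),
        "ratio_window": int(ratio_window),
        "pause_window": int(pause_window),
        "min_prominence": min_prominence,
        "min_distance": int(min_distance),
        "velocity": params.velocity,
        "t_total": params.t_total,
        "unit": {
            "name": unit.name,
            "chrom": unit.chrom,
            "start": unit.start,
            "end": unit.end,
            "strand": unit.strand,
        },
        "condition_test": condition_test,
        "condition_ref": condition_ref,
        "n_samples": {c: len(reps) for c, reps in sorted(by_condition.items())},
    }
    return ComparisonReport(
        unit=unit,
        params=params,
        condition_test=condition_test,
        condition_ref=condition_ref,
        aggregates=aggregates,
        fractions=display,
        occupancy=occupancy,
        delta_log2=delta,
        pauses=pauses,
        matched_pauses=_match_pauses(
            pauses[condition_ref], pauses[condition_test], min_distance
        ),
        regions=regions,
        settings=settings,
    )
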