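"""Per-nucleotide occupancy representations.

The pipeline stages mirror the standard nascent-transcript 3'-end analysis:
read 3' ends are counted per unit position, a pseudocount is added to every
position, counts are normalised to fractions of reads for the unit, tracks
are smoothed with a Blackman window, and biological replicates are
aggregated as the per-position median with a second-to-third-quartile band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ribopause.io import ReadRecord, TranscriptionUnit, to_unit_coordinates

logger = logging.getLogger(__name__)

PROFILE_KINDS = (
    "count",
    "fraction",
    "smoothed_fraction",
    "occupancy_time_seconds",
    "log2_ratio",
)

#: Default smoothing windows (nt): profiles are displayed after ~30-nt
#: smoothing and condition ratios computed after ~50-nt smoothing; a
#: symmetric kernel needs odd support, so the nearest odd values are used.
DEFAULT_PROFILE_WINDOW = 31
DEFAULT_RATIO_WINDOW = 51


class ProfileError(ValueError):
    """Raised for invalid profile inputs or incompatible operations."""


@dataclass(frozen=True)
class PositionProfile:
    """A per-nucleotide numeric track over a transcription unit.

    meta records provenance: sample_id / condition / replicate, the
    smoothing window and the pseudocount where applied.
    """

    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ProfileError("profile values must be a nonempty 1-D vector")
        if self.kind not in PROFILE_KINDS:
            raise ProfileError(f"unknown profile kind {self.kind!r}")
        if self.kind in ("count", "fraction", "smoothed_fraction"):
            if np.any(values < 0):
                raise ProfileError(f"{self.kind} profile has negative values")
        if self.kind in ("fraction", "smoothed_fraction"):
            total = values.sum()
            if abs(total - 1.0) > 1e-9:
                raise ProfileError(
                    f"{self.kind} profile sums to {total!r}, expected 1"
                )

    def __len__(self) -> int:
        return int(self.values.size)

    def with_values(self, values: np.ndarray, kind: str | None = None,
                    **meta_updates) -> "PositionProfile":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return PositionProfile(values, kind or self.kind, meta)


@dataclass(frozen=True)
class AggregateProfile:
    """Replicate aggregate: per-position median with the second-to-third
    quartile envelope, the display convention for paired biological
    replicates (for two replicates the median equals their mean)."""

    median: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    n_replicates: int
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("median", "band_low", "band_high"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.median.shape == self.band_low.shape == self.band_high.shape):
            raise ProfileError("aggregate vectors must share one length")
        if np.any(self.band_low > self.median + 1e-12) or np.any(
            self.median > self.band_high + 1e-12
        ):
            raise ProfileError("band_low <= median <= band_high must hold")


# ---------------------------------------------------------------------------
# counting and normalisation


def count_three_prime_ends(
    reads: Iterable[ReadRecord], unit: TranscriptionUnit
) -> PositionProfile:
    """Sum read weights by the unit position of each read's 3' end.

    Reads whose 3' end falls outside the unit (or on the opposite strand /
    another chromosome) contribute nothing. Total counts equal the total
    weight of in-unit reads.
    """
    values = np.zeros(unit.length)
    for read in reads:
        position = to_unit_coordinates(read, unit)
        if position is not None:
            values[position] += read.weight
    return PositionProfile(values, "count", {"unit": unit.name})


def add_pseudocounts(profile: PositionProfile, alpha: float = 1.0) -> PositionProfile:
    """Add a constant pseudocount to every position (recorded in meta)."""
    if profile.kind != "count":
        raise ProfileError(f"pseudocounts apply to count profiles, got {profile.kind}")
    if alpha < 0:
        raise ProfileError(f"pseudocount must be nonnegative, got {alpha}")
    return profile.with_values(profile.values + alpha, pseudocount=alpha)


def to_fractions(profile: PositionProfile) -> PositionProfile:
    """Normalise counts to fractions of reads for the transcription unit."""
    if profile.kind != "count":
        raise ProfileError(f"to_fractions expects a count profile, got {profile.kind}")
    total = profile.values.sum()
    if total <= 0:
        raise ProfileError(
            "cannot normalise an all-zero count profile; add pseudocounts "
            "(add_pseudocounts with alpha > 0) before converting to fractions"
        )
    return profile.with_values(profile.values / total, kind="fraction")


# ---------------------------------------------------------------------------
# smoothing


def _as_odd_window(window: int, length: int) -> int:
    window = int(window)
    if window < 3:
        raise ProfileError(f"smoothing window must be >= 3, got {window}")
    if window % 2 == 0:
        logger.info("adjusting even smoothing window %d to %d", window, window + 1)
        window += 1
    if window > length:
        raise ProfileError(
            f"smoothing window {window} exceeds profile length {length}"
        )
    return window


def blackman_kernel(window: int) -> np.ndarray:
    """Blackman taper w(n) = 0.42 - 0.5 cos(2 pi n/(M-1)) + 0.08 cos(4 pi n/(M-1)),
    normalised to unit sum."""
    # endpoints are analytically zero; clip the ~1e-17 float noise so
    # smoothing can never produce negative values
    kernel = np.clip(np.blackman(window), 0.0, None)
    return kernel / kernel.sum()

def blackman_smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Same-length Blackman smoothing with edge renormalisation.

    At positions closer than half a window to a boundary the kernel is
    renormalised over the in-bounds support, so a constant input is an
    exact fixed point and no artificial decay appears at the unit edges.
    """
    values = np.asarray(values, dtype=float)
    window = _as_odd_window(window, values.size)
    kernel = blackman_kernel(window)
    smoothed = np.convolve(values, kernel, mode="same")
    coverage = np.convolve(np.ones_like(values), kernel, mode="same")
    return smoothed / coverage


def smooth_blackman(profile: PositionProfile, window: int = DEFAULT_PROFILE_WINDOW) -> PositionProfile:
    """Blackman-smooth a fraction profile.

    The output is renormalised to unit sum (edge renormalisation can move
    total mass by a negligible but nonzero amount) and keeps kind
    smoothed_fraction with the window recorded in meta.
    """
    if profile.kind not in ("fraction", "smoothed_fraction"):
        raise ProfileError(
            f"smooth_blackman expects a fraction profile, got {profile.kind}"
        )
    window = _as_odd_window(window, profile.values.size)
    smoothed = blackman_smooth(profile.values, window)
    smoothed = smoothed / smoothed.sum()
    return profile.with_values(smoothed, kind="smoothed_fraction", window=window)


# ---------------------------------------------------------------------------
# replicate aggregation


def aggregate_replicates(profiles: Sequence[PositionProfile]) -> AggregateProfile:
    """Per-position median and linear-interpolation quartile band.

    The band spans the second to third quartile (Q2..Q3) across replicates;
    with two replicates the median is their mean and the band reaches
    three quarters of the way to the larger value.
    """
    if len(profiles) < 2:
        raise ProfileError("replicate aggregation needs at least two profiles")
    kinds = {p.kind for p in profiles}
    if len(kinds) != 1:
        raise ProfileError(f"cannot aggregate mixed profile kinds {sorted(kinds)}")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise ProfileError(f"replicate profiles differ in length: {sorted(lengths)}")
    stack = np.vstack([p.values for p in profiles])
    q2, q3 = np.percentile(stack, [50, 75], axis=0)
    meta = {k: v for k, v in profiles[0].meta.items() if k not in ("replicate", "sample_id")}
    return AggregateProfile(
        median=q2,
        band_low=q2,
        band_high=q3,
        n_replicates=len(profiles),
        kind=kinds.pop(),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# read classification


def classify_reads(
    reads: Sequence[ReadRecord],
    categories: Mapping[str, Sequence[tuple[str, int, int]]],
    priority: Sequence[str] | None = None,
) -> dict[str, float]:
    """Fraction of total read weight per gene category.

    categories maps a category name to genomic intervals (chrom, start,
    end). Each read is assigned to the category with maximal overlap; ties
    go to the earlier category in the priority order (the mapping order by
    default). Reads overlapping nothing count as "unassigned". Fractions
    sum to 1.
    """
    reads = list(reads)
    if not reads:
        raise ProfileError("cannot classify an empty read set")
    order = list(priority) if priority is not None else list(categories)
    unknown = set(order) - set(categories)
    if unknown:
        raise ProfileError(f"priority names absent from categories: {sorted(unknown)}")
    weights = {name: 0.0 for name in order}
    weights["unassigned"] = 0.0
    for read in reads:
        best_name = "unassigned"
        best_overlap = 0
        for name in order:
            overlap = 0
            for chrom, start, end in categories[name]:
                if chrom != read.chrom:
                    continue
                overlap += max(0, min(end, read.end) - max(start, read.start))
            if overlap > best_overlap:
                best_overlap = overlap
                best_name = name
        weights[best_name] += read.weight
    total = sum(weights.values())
    if total <= 0:
        raise ProfileError("total read weight is zero")
    return {name: weight / total for name, weight in weights.items()}
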