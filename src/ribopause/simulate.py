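"""Stochastic RNAPI elongation simulator.

Generates CRAC-style synthetic datasets with known pause structure. The
kinetic model assumes independent polymerases at constant initiation flux,
so the steady-state occupancy density at a position is proportional to the
polymerase dwell time there. Under that assumption the expected fraction
of read 3' ends at position i is dwell_i / sum(dwell), which gives every
downstream pipeline stage an exact analytic oracle. Polymerase-polymerase
exclusion (TASEP-style traffic) is deliberately not modelled: the
occupancy-time conversion used by the analysis itself assumes the simple
proportionality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ribopause.io import ReadRecord, TranscriptionUnit

#: Dwell-time baseline (seconds per nucleotide) implied by the canonical
#: 40 nt/s average velocity of yeast RNAPI.
DEFAULT_BASELINE_DWELL = 0.025


class SimulationError(ValueError):
    """Raised for invalid simulator parameters."""


@dataclass(frozen=True)
class ElongationModel:
    """Ground-truth per-position dwell times with pause annotations.

    dwell[i] is the mean time (seconds) the polymerase spends at unit
    position i; pause positions carry dwell = local baseline x multiplier.
    """

    dwell: np.ndarray
    pause_positions: tuple[int, ...] = ()
    pause_multipliers: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        dwell = np.asarray(self.dwell, dtype=float)
        object.__setattr__(self, "dwell", dwell)
        if dwell.ndim != 1 or dwell.size == 0:
            raise SimulationError("dwell must be a nonempty 1-D vector")
        if not np.all(np.isfinite(dwell)) or np.any(dwell <= 0):
            raise SimulationError("dwell values must be strictly positive and finite")
        positions = tuple(int(p) for p in self.pause_positions)
        multipliers = tuple(float(m) for m in self.pause_multipliers)
        object.__setattr__(self, "pause_positions", positions)
        object.__setattr__(self, "pause_multipliers", multipliers)
        if len(positions) != len(multipliers):
            raise SimulationError("one multiplier is required per pause position")
        if len(set(positions)) != len(positions):
            raise SimulationError("pause positions must be unique")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise SimulationError("pause positions must be sorted")
        if positions and not (0 <= positions[0] and positions[-1] < dwell.size):
            raise SimulationError(
                f"pause positions must lie within [0, {dwell.size})"
            )
        if any(m < 1 for m in multipliers):
            raise SimulationError("pause multipliers must be >= 1")

    @property
    def unit_length(self) -> int:
        return int(self.dwell.size)

    @property
    def total_dwell(self) -> float:
        """Total transit time (seconds) across the unit."""
        return float(self.dwell.sum())

    @property
    def velocity_mean(self) -> float:
        """Mean elongation velocity (nt/s) implied by the dwell profile."""
        return self.unit_length / self.total_dwell


def build_dwell_profile(
    unit_length: int,
    baseline_dwell: float = DEFAULT_BASELINE_DWELL,
    pause_positions: Sequence[int] = (),
    pause_multipliers: Sequence[float] = (),
    ets5_enrichment: tuple[float, int] | None = None,
) -> ElongationModel:
    """Construct a dwell-time model: flat baseline, optional uniformly
    elevated 5' block, and point pauses.

    ets5_enrichment is (factor, extent): dwell over the first `extent`
    positions is multiplied by `factor`, emulating the strong 5'ETS
    occupancy enrichment seen in RNAPI profiles. A pause inside that block
    multiplies the elevated local baseline.
    """
    if unit_length <= 0:
        raise SimulationError("unit_length must be positive")
    if baseline_dwell <= 0:
        raise SimulationError("baseline_dwell must be positive")
    dwell = np.full(unit_length, float(baseline_dwell))
    if ets5_enrichment is not None:
        factor, extent = ets5_enrichment
        if factor < 1:
            raise SimulationError("5'ETS enrichment factor must be >= 1")
        if not (0 < extent <= unit_length):
            raise SimulationError(
                f"5'ETS extent {extent} outside (0, {unit_length}]"
            )
        dwell[: int(extent)] *= float(factor)
    order = np.argsort(pause_positions)
    positions = tuple(int(pause_positions[i]) for i in order)
    multipliers = tuple(float(pause_multipliers[i]) for i in order)
    for position, multiplier in zip(positions, multipliers):
        if not (0 <= position < unit_length):
            raise SimulationError(
                f"pause position {position} outside [0, {unit_length})"
            )
        dwell[position] *= multiplier
    return ElongationModel(dwell, positions, multipliers)


def expected_fractions(model: ElongationModel):
    """Analytic steady-state fraction of 3' ends per position.

    f_i = dwell_i / sum_j dwell_j; sums to 1 by construction. Returned as a
    fraction-kind PositionProfile so it can flow through the same pipeline
    stages as read-derived profiles.
    """
    from ribopause.profiles import PositionProfile

    return PositionProfile(
        model.dwell / model.total_dwell, "fraction", {"source": "expected"}
    )


# ---------------------------------------------------------------------------
# read-length samplers


@dataclass(frozen=True)
class GeometricLengths:
    """Truncated geometric read lengths: min_length + Geometric - 1,
    parameterised by the target mean. Default mean 30 nt, minimum 15 nt,
    a plausible CRAC insert-size model."""

    mean: float = 30.0
    min_length: int = 15

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise SimulationError("min_length must be positive")
        if self.mean <= self.min_length:
            raise SimulationError("mean read length must exceed min_length")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = 1.0 / (self.mean - self.min_length + 1)
        return self.min_length + rng.geometric(p, size=n) - 1


@dataclass(frozen=True)
class FixedLengths:
    """Constant read length."""

    length: int = 30

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise SimulationError("read length must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.length, dtype=int)


def simulate_reads(
    model: ElongationModel,
    unit: TranscriptionUnit,
    n_reads: int,
    read_length_sampler: GeometricLengths | FixedLengths | None = None,
    seed: int = 0,
) -> list[ReadRecord]:
    """Draw CRAC-style reads whose 3' ends sample the steady-state
    occupancy distribution.

    3'-end unit positions are multinomial over expected_fractions(model);
    each read extends upstream by a sampled length, truncated at the unit
    5' boundary. Genomic coordinates honour the unit strand: the 3' end
    maps to the rightmost base for plus-strand units and the leftmost base
    for minus-strand units.
    """
    if n_reads <= 0:
        raise SimulationError("n_reads must be positive")
    if model.unit_length != unit.length:
        raise SimulationError(
            f"model length {model.unit_length} != unit length {unit.length}"
        )
    sampler = read_length_sampler or GeometricLengths()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, expected_fractions(model).values)
    ends = np.repeat(np.arange(model.unit_length), counts)
    lengths = sampler.sample(rng, n_reads)
    starts = np.maximum(ends - lengths + 1, 0)  # truncate at the 5' boundary
    reads = []
    for i, (ustart, uend3) in enumerate(zip(starts, ends)):
        if unit.strand == "+":
            gstart = unit.start + int(ustart)
            gend = unit.start + int(uend3) + 1
        else:
            gstart = unit.end - 1 - int(uend3)
            gend = unit.end - int(ustart)
        reads.append(
            ReadRecord(unit.chrom, gstart, gend, unit.strand, name=f"read{i}")
        )
    return reads


# ---------------------------------------------------------------------------
# condition pairs


@dataclass
class SimulatedDataset:
    """Reads per (condition, replicate) plus the generating ground truth."""

    reads_by_sample: dict[tuple[str, int], list[ReadRecord]]
    truth: dict[str, ElongationModel]
    unit: TranscriptionUnit
    seed: int
    n_reads: int

    def conditions(self) -> list[str]:
        return sorted(self.truth)

    def write(self, outdir: str | Path) -> Path:
        """Persist reads as BED6, truth dwell as bedGraph, and a JSON
        sidecar with pause annotations and seeds."""
        from ribopause.io import write_track

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (condition, replicate), reads in sorted(self.reads_by_sample.items()):
            bed = outdir / f"{condition}_rep{replicate}.bed"
            with open(bed, "w") as handle:
                for read in reads:
                    handle.write(
                        f"{read.chrom}\t{read.start}\t{read.end}\t{read.name}\t0\t{read.strand}\n"
                    )
        sidecar: dict = {"seed": self.seed, "n_reads": self.n_reads, "conditions": {}}
        for condition, model in sorted(self.truth.items()):
            write_track(model.dwell, self.unit, outdir / f"{condition}_dwell.bedgraph")
            sidecar["conditions"][condition] = {
                "pause_positions": list(model.pause_positions),
                "pause_multipliers": list(model.pause_multipliers),
                "total_dwell_seconds": model.total_dwell,
            }
        with open(outdir / "truth.json", "w") as handle:
            json.dump(sidecar, handle, indent=2, sort_keys=True)
        return outdir


def attenuate_pauses(model: ElongationModel, attenuation: float) -> ElongationModel:
    """Depleted-condition model: each pause multiplier m becomes
    1 + attenuation * (m - 1); attenuation 1 leaves the model unchanged,
    smaller values flatten the pauses toward the local baseline."""
    if not (0 < attenuation <= 1):
        raise SimulationError("pause attenuation must be in (0, 1]")
    dwell = model.dwell.copy()
    new_multipliers = []
    for position, multiplier in zip(model.pause_positions, model.pause_multipliers):
        attenuated = 1 + attenuation * (multiplier - 1)
        dwell[position] *= attenuated / multiplier
        new_multipliers.append(attenuated)
    return ElongationModel(dwell, model.pause_positions, tuple(new_multipliers))


def simulate_condition_pair(
    model_wt: ElongationModel,
    pause_attenuation: float,
    n_replicates: int = 2,
    n_reads: int = 500_000,
    seed: int = 0,
    unit: TranscriptionUnit | None = None,
    read_length_sampler: GeometricLengths | FixedLengths | None = None,
    condition_names: tuple[str, str] = ("wildtype", "depleted"),
) -> SimulatedDataset:
    """Simulate a wild-type / pause-attenuated condition pair.

    Replicates use seeds at fixed offsets from the master seed
    (seed + 1000*condition_index + replicate_index) so streams are
    independent but fully reproducible.
    """
    if n_replicates < 1:
        raise SimulationError("need at least one replicate")
    if unit is None:
        unit = TranscriptionUnit(
            "rDNA", 0, model_wt.unit_length, "+", name="rdna_unit"
        )
    models = {
        condition_names[0]: model_wt,
        condition_names[1]: attenuate_pauses(model_wt, pause_attenuation),
    }
    reads_by_sample: dict[tuple[str, int], list[ReadRecord]] = {}
    for ci, condition in enumerate(condition_names):
        for replicate in range(1, n_replicates + 1):
            sub_seed = seed + 1000 * ci + replicate
            reads_by_sample[(condition, replicate)] = simulate_reads(
                models[condition], unit, n_reads, read_length_sampler, seed=sub_seed
            )
    return SimulatedDataset(reads_by_sample, models, unit, seed, n_reads)


# ---------------------------------------------------------------------------
# qPCR fixture generation


def simulate_qpcr(
    true_enrichment: float,
    ct_reference: float = 20.0,
    dilution_ip: float = 20.0,
    dilution_input: float = 100.0,
    noise_sd: float = 0.0,
    n_technical: int = 3,
    seed: int = 0,
    amplicon: str = "amplicon",
):
    """Generate CT replicate sets for a programmed ChIP enrichment.

    The generated CTs embed the dilution effect (a d-fold more dilute
    template shifts CT by +log2 d), so dilution-corrected 2^dCT analysis
    recovers true_enrichment exactly at noise_sd = 0; with equal dilutions
    the uncorrected convention coincides.
    """
    from ribopause.qpcr import QpcrMeasurement

    if true_enrichment <= 0:
        raise SimulationError("true_enrichment must be positive")
    if dilution_ip <= 0 or dilution_input <= 0:
        raise SimulationError("dilution factors must be positive")
    if n_technical < 1:
        raise SimulationError("need at least one technical replicate")
    rng = np.random.default_rng(seed)
    ct_ip = float(ct_reference)
    ct_input = ct_ip + np.log2(true_enrichment * dilution_ip / dilution_input)
    return QpcrMeasurement(
        ct_ip=tuple(ct_ip + rng.normal(0.0, noise_sd, n_technical)),
        ct_input=tuple(ct_input + rng.normal(0.0, noise_sd, n_technical)),
        dilution_ip=dilution_ip,
        dilution_input=dilution_input,
        amplicon=amplicon,
    )
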