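"""qPCR cycle-threshold arithmetic.

ChIP-qPCR enrichment by the 2^dCT formula (dCT = mean input CT minus mean
IP CT, optionally corrected for the different input/IP dilution factors)
and RT-qPCR relative expression by the ddCq method against a reference
gene. Technical replicates are summarised by their mean; no outlier
rejection is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class QpcrError(ValueError):
    """Raised for invalid CT inputs."""


def _validate_cts(cts: Sequence[float], label: str) -> tuple[float, ...]:
    values = tuple(float(c) for c in cts)
    if not values:
        raise QpcrError(f"{label}: need at least one technical replicate")
    if not all(math.isfinite(c) and c > 0 for c in values):
        raise QpcrError(f"{label}: CT values must be finite and positive")
    return values


@dataclass(frozen=True)
class QpcrMeasurement:
    """CT replicate sets for one amplicon, with dilution factors.

    Defaults follow the common ChIP workflow where input (whole-cell
    extract) DNA is diluted 100-fold and IP DNA 20-fold before qPCR.
    """

    ct_ip: tuple[float, ...]
    ct_input: tuple[float, ...]
    dilution_ip: float = 20.0
    dilution_input: float = 100.0
    amplicon: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ct_ip", _validate_cts(self.ct_ip, "ct_ip"))
        object.__setattr__(self, "ct_input", _validate_cts(self.ct_input, "ct_input"))
        if self.dilution_ip <= 0 or self.dilution_input <= 0:
            raise QpcrError("dilution factors must be positive")


@dataclass(frozen=True)
class RelativeExpressionInput:
    """CTs for the ddCq design: target and reference gene, in the test
    sample and the calibrator sample."""

    ct_target_test: float
    ct_target_cal: float
    ct_ref_test: float
    ct_ref_cal: float

    def __post_init__(self) -> None:
        for name in ("ct_target_test", "ct_target_cal", "ct_ref_test", "ct_ref_cal"):
            if not math.isfinite(getattr(self, name)):
                raise QpcrError(f"{name} must be finite")


@dataclass(frozen=True)
class ChipEnrichmentResult:
    """2^dCT abundance with its provenance (dCT and correction flag)."""

    abundance: float
    delta_ct: float
    dilution_corrected: bool
    amplicon: str = ""

    def __float__(self) -> float:
        return self.abundance


def chip_enrichment(
    m: QpcrMeasurement, apply_dilution_correction: bool = False
) -> ChipEnrichmentResult:
    """Relative abundance of immunoprecipitated material by 2^dCT.

    dCT = mean(ct_input) - mean(ct_ip); abundance = 2^dCT, multiplied by
    dilution_input / dilution_ip when the correction is enabled. The flag
    is recorded in the result so either convention is reproducible.
    """
    delta_ct = float(np.mean(m.ct_input) - np.mean(m.ct_ip))
    abundance = 2.0 ** delta_ct
    if apply_dilution_correction:
        abundance *= m.dilution_input / m.dilution_ip
    return ChipEnrichmentResult(
        abundance=abundance,
        delta_ct=delta_ct,
        dilution_corrected=apply_dilution_correction,
        amplicon=m.amplicon,
    )


def normalize_to_control(signal_tagged: float, signal_untagged: float) -> float:
    """Fold enrichment of a tagged strain over the untagged control."""
    tagged = float(signal_tagged)
    untagged = float(signal_untagged)
    if untagged <= 0:
        raise QpcrError("untagged control signal must be positive")
    return tagged / untagged


def relative_expression(x: RelativeExpressionInput) -> float:
    """Fold change by the ddCq method: 2^-((dCq_test) - (dCq_calibrator)),
    with dCq = CT_target - CT_reference."""
    ddcq = (x.ct_target_test - x.ct_ref_test) - (x.ct_target_cal - x.ct_ref_cal)
    return 2.0 ** (-ddcq)


def analyze_table(table: pd.DataFrame, mode: str = "chip",
                  apply_dilution_correction: bool = False) -> pd.DataFrame:
    """Tidy-table driver for CT data.

    chip mode expects columns (sample, amplicon, role, dilution, ct) with
    role IP/input and returns one 2^dCT abundance per (sample, amplicon).
    ddcq mode expects columns (sample, gene, role, ct) with role
    target/reference and sample roles test/calibrator encoded in a
    'group' column.
    """
    if mode == "chip":
        rows = []
        for (sample, amplicon), chunk in table.groupby(["sample", "amplicon"]):
            roles = {role.lower(): sub for role, sub in chunk.groupby(chunk["role"].str.lower())}
            if "ip" not in roles or "input" not in roles:
                raise QpcrError(
                    f"sample {sample!r} amplicon {amplicon!r}: need both IP and input rows"
                )
            m = QpcrMeasurement(
                ct_ip=tuple(roles["ip"]["ct"].astype(float)),
                ct_input=tuple(roles["input"]["ct"].astype(float)),
                dilution_ip=float(roles["ip"]["dilution"].iloc[0]),
                dilution_input=float(roles["input"]["dilution"].iloc[0]),
                amplicon=str(amplicon),
            )
            result = chip_enrichment(m, apply_dilution_correction)
            rows.append(
                {
                    "sample": sample,
                    "amplicon": amplicon,
                    "delta_ct": result.delta_ct,
                    "abundance": result.abundance,
                    "dilution_corrected": result.dilution_corrected,
                }
            )
        return pd.DataFrame(rows)
    if mode == "ddcq":
        rows = []
        means = (
            table.assign(
                role=table["role"].str.lower(), group=table["group"].str.lower()
            )
            .groupby(["gene", "group", "role"])["ct"].mean()
        )
        for gene in table["gene"].unique():
            x = RelativeExpressionInput(
                ct_target_test=means[(gene, "test", "target")],
                ct_target_cal=means[(gene, "calibrator", "target")],
                ct_ref_test=means[(gene, "test", "reference")],
                ct_ref_cal=means[(gene, "calibrator", "reference")],
            )
            rows.append({"gene": gene, "fold_change": relative_expression(x)})
        return pd.DataFrame(rows)
    raise QpcrError(f"unknown qPCR analysis mode {mode!r}")
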