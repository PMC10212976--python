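import numpy as np
import pytest

from ribopause import (
    TranscriptionUnit,
    Region,
    build_dwell_profile,
    load_builtin_unit,
)


@pytest.fixture(scope="session")
def rdna_unit() -> TranscriptionUnit:
    """The packaged 7800-nt rDNA unit with 5'ETS = [0, 1300)."""
    return load_builtin_unit()


@pytest.fixture
def plus_unit() -> TranscriptionUnit:
    return TranscriptionUnit("rDNA", 100, 7900, "+", name="plus_unit")


@pytest.fixture
def minus_unit() -> TranscriptionUnit:
    return TranscriptionUnit("rDNA", 100, 7900, "-", name="minus_unit")


@pytest.fixture
def tiny_unit() -> TranscriptionUnit:
    return TranscriptionUnit(
        "chrT", 0, 10, "+", name="tiny",
        regions=(Region("left", 0, 4), Region("right", 4, 10)),
    )


@pytest.fixture(scope="session")
def pause_model():
    """7800-nt model, 25-ms baseline, 20 well-separated x10 point pauses."""
    positions = list(range(200, 8000, 390))[:20]
    return build_dwell_profile(7800, 0.025, positions, [10.0] * 20)
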