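import numpy as np
import pytest

from axispeaks.intervals import ChromSizes, GenomicInterval, PeakSet
from axispeaks.simulate import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """One fully generated default-condition scenario shared by read-only tests."""
    return generate_scenario(ScenarioConfig(seed=20260928))


@pytest.fixture()
def sizes():
    return ChromSizes({"chr1": 20_000, "chr2": 20_000})


def make_peaks(spans, label="peaks"):
    return PeakSet(label, [GenomicInterval(*s) for s in spans]).sorted()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
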