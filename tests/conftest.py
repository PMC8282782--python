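import numpy as np
import pytest

from cryoperf import GeneratorConfig, SubsetPoint

# Published per-subset summary values used as worked examples:
# (B-factor [A^2], resolution from 100 k particles [A],
#  particles to reach 3 A [x10^3]).
TABLE2 = {
    "+VPP": (188.0, 3.53, 1787.0),
    "-VPP": (135.5, 3.14, 191.0),
    "+ZLF": (113.6, 2.77, 33.8),
    "-ZLF": (134.7, 3.03, 118.7),
    "+OLA": (91.2, 2.60, 19.1),
    "-OLA": (87.1, 2.63, 23.6),
}


@pytest.fixture
def table2():
    return TABLE2


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def cfg():
    return GeneratorConfig(seed=7)


def exact_line_points(slope, offset, counts):
    """SubsetPoints lying exactly on 1/d^2 = slope*ln N + offset."""
    points = []
    for n in counts:
        n = int(round(n))
        y = slope * np.log(n) + offset
        points.append(SubsetPoint(n, float(y ** -0.5)))
    return points
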