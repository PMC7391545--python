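from fractions import Fraction

import pytest
from hypothesis import settings

import haplobreed as hb

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# exact dyadic values of the chain at generation 15 from A0 = 1
F15 = Fraction(31171, 32768)  # 0.951263427734375
D15 = Fraction(15339, 16384)  # 0.93621826171875


@pytest.fixture
def pure_a() -> hb.CrossTypeDistribution:
    """Most-heterozygotic founding cross: [x,y] female x [z] male."""
    return hb.CrossTypeDistribution.pure("A")


@pytest.fixture(scope="session")
def exact_trajectory_30() -> hb.Trajectory:
    """Exact-rational chain trajectory to generation 30 from A0 = 1."""
    return hb.iterate_trajectory(hb.CrossTypeDistribution.pure("A"), 30)
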