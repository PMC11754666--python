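import pytest
from hypothesis import HealthCheck, settings

import bendscan as bs

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

# 14-bp target strand: TTTG PAM at -4..-1 when built with first_index=-4,
# but the default layout used throughout starts at -3.
SEQUENCE = "GCTTTGACTGACGT"


@pytest.fixture
def sequence() -> str:
    return SEQUENCE


@pytest.fixture
def ideal_duplex():
    return bs.build_ideal_duplex(SEQUENCE)


@pytest.fixture
def bent_duplex():
    spec = bs.DistortionSpec(bend=53.0, direction=30.0, extra_untwist=28.0)
    duplex, truth = bs.generate_bent_duplex(SEQUENCE, spec)
    return duplex, truth


def pairing_map(duplex):
    """The (ts_num, nts_num, pam_index) map matching the built-in numbering."""
    n = len(duplex)
    return [(k + 1, n - k, bp.pam_index) for k, bp in enumerate(duplex.pairs)]
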