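import pytest
from hypothesis import HealthCheck, settings

from mirduplex import MatureMiRNA, RnaSequence
from mirduplex.sequences import (
    GRF2_SITE,
    MIR396A,
    MIR396B,
    MIR396B_7AG,
    MIR396_78INSG,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def mir396a() -> MatureMiRNA:
    return MatureMiRNA("ath-miR396a", "ath", "miR396", RnaSequence("ath-miR396a", MIR396A))


@pytest.fixture
def mir396_insg() -> MatureMiRNA:
    return MatureMiRNA("osa-miR396e", "osa", "miR396",
                       RnaSequence("osa-miR396e", MIR396_78INSG))


@pytest.fixture
def grf2_site() -> RnaSequence:
    return RnaSequence("GRF2-site", GRF2_SITE)
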