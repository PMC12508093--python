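import pytest
from hypothesis import HealthCheck, settings

from shoalmix import (
    NATIVE,
    RANGE_EXTENDING,
    ForagingRecord,
    ShoalRecord,
    SpeciesCatalog,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


@pytest.fixture
def catalog():
    return SpeciesCatalog(
        {
            "sp1": NATIVE,
            "sp2": NATIVE,
            "sp3": RANGE_EXTENDING,
            "sp4": RANGE_EXTENDING,
        }
    )


@pytest.fixture
def shoal(catalog):
    def _make(shoal_id="s1", counts=None, location="locA", observer="obs1"):
        return ShoalRecord(
            shoal_id=shoal_id,
            location_id=location,
            observer_id=observer,
            counts=counts or {"sp1": 3, "sp3": 2},
        )

    return _make


@pytest.fixture
def foraging_record():
    def _make(
        individual_id="f1",
        species="sp1",
        length_cm=15.0,
        shoal_size=5,
        shoal_type="mono_specific",
        duration_s=60.0,
        n_bites=30,
        n_bouts=5,
    ):
        return ForagingRecord(
            individual_id=individual_id,
            species=species,
            length_cm=length_cm,
            shoal_size=shoal_size,
            shoal_type=shoal_type,
            location_id="locA",
            observer_id="obs1",
            duration_s=duration_s,
            n_bites=n_bites,
            n_bouts=n_bouts,
        )

    return _make
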