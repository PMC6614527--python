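import pytest

from ecrplan import (CityGenSpec, generate_city, read_hospitals,
                     read_incidence, read_suburbs, read_travel_matrix)
from ecrplan.datasets import demo_city_dir


@pytest.fixture(scope="session")
def demo_bundle():
    """The shipped 226-suburb, 5-hospital demo city."""
    d = demo_city_dir()
    incidence = read_incidence(d / "incidence.csv")
    suburbs = read_suburbs(d / "suburbs.csv", incidence.bands)
    hospitals = read_hospitals(d / "hospitals.csv")
    matrix = read_travel_matrix(
        d / "travel.csv", "wide",
        suburb_ids=[s.id for s in suburbs],
        hospital_ids=[h.id for h in hospitals])
    return suburbs, hospitals, matrix, incidence


@pytest.fixture(scope="session")
def small_city():
    """A quick 40-suburb, 4-hospital synthetic city."""
    return generate_city(CityGenSpec(n_suburbs=40, n_hospitals=4, seed=7))
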