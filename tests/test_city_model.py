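import math

import numpy as np
import pandas as pd
import pytest

from ecrplan import (AgeBand, IncidenceTable, read_suburbs,
                     read_travel_matrix, validate_city, write_suburbs,
                     write_travel_matrix)
from ecrplan.city_model import check_band_schema

TWO_BANDS = (AgeBand(0, 64), AgeBand(65, None, "65+"))


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestAgeBand:
    def test_parse_labels(self):
        assert AgeBand.parse("0-64") == AgeBand(0, 64)
        assert AgeBand.parse("85+").open_ended
        with pytest.raises(ValueError):
            AgeBand.parse("old")

    @pytest.mark.parametrize("bands, message", [
        ((AgeBand(0, 64), AgeBand(70, None)), "gap"),
        ((AgeBand(0, 64), AgeBand(60, None)), "overlap"),
        ((AgeBand(5, 64), AgeBand(65, None)), "start at 0"),
        ((AgeBand(0, 64),), "open-ended"),
    ])
    def test_schema_violations_are_named(self, bands, message):
        with pytest.raises(ValueError, match=message):
            check_band_schema(bands)


class TestReadSuburbs:
    def test_parses_rows_and_bands(self, tmp_path):
        p = _write(tmp_path, "s.csv",
                   "id,name,lat,lon,0-64,65+\n"
                   "S1,Alpha,-33.9,151.0,1200,300\n"
                   "S2,Beta,-33.8,151.1,800,100\n"
                   "S3,Gamma,-33.7,151.2,0,50\n")
        suburbs = read_suburbs(p, TWO_BANDS)
        assert len(suburbs) == 3
        assert all(len(s.population) == 2 for s in suburbs)
        assert suburbs[0].population[AgeBand(0, 64)] == 1200
        assert suburbs[2].total_population == 50

    def test_duplicate_id_names_the_offender(self, tmp_path):
        p = _write(tmp_path, "s.csv",
                   "id,name,lat,lon,0-64,65+\n"
                   "S1,A,-33.9,151.0,10,1\nS1,B,-33.8,151.1,20,2\n")
        with pytest.raises(ValueError, match="S1"):
            read_suburbs(p, TWO_BANDS)

    def test_unknown_band_column_named(self, tmp_path):
        p = _write(tmp_path, "s.csv",
                   "id,name,lat,lon,0-64,65+,bogus\nS1,A,-33.9,151.0,10,1,7\n")
        with pytest.raises(ValueError, match="bogus"):
            read_suburbs(p, TWO_BANDS)

    def test_negative_count_rejected(self, tmp_path):
        p = _write(tmp_path, "s.csv",
                   "id,name,lat,lon,0-64,65+\nS1,A,-33.9,151.0,-5,1\n")
        with pytest.raises(ValueError, match="negative"):
            read_suburbs(p, TWO_BANDS)


def test_round_trip_full_city(demo_bundle, tmp_path):
    """Writing then re-reading a 226-suburb bundle is value-identical."""
    suburbs, hospitals, matrix, incidence = demo_bundle
    write_suburbs(suburbs, tmp_path / "s.csv")
    back = read_suburbs(tmp_path / "s.csv", incidence.bands)
    assert [s.id for s in back] == [s.id for s in suburbs]
    for a, b in zip(suburbs, back):
        assert a.population == b.population
        assert a.lat == pytest.approx(b.lat) and a.lon == pytest.approx(b.lon)

    write_travel_matrix(matrix, tmp_path / "t.csv", "wide")
    m2 = read_travel_matrix(tmp_path / "t.csv", "wide")
    # shipped file carries 2 decimals, so round-trip is exact at that grain
    np.testing.assert_allclose(m2.minutes, matrix.minutes, atol=0.005)


class TestTravelMatrixIO:
    def test_wide_2x2(self, tmp_path):
        p = _write(tmp_path, "t.csv",
                   "suburb_id,HA,HB\nS1,10,40\nS2,35,12\n")
        m = read_travel_matrix(p, "wide")
        np.testing.assert_array_equal(m.minutes, [[10, 40], [35, 12]])
        assert m.suburb_ids == ["S1", "S2"] and m.hospital_ids == ["HA", "HB"]

    def test_long_missing_pair_becomes_unreachable(self, tmp_path):
        p = _write(tmp_path, "t.csv",
                   "suburb_id,hospital_id,minutes\n"
                   "S1,HA,10\nS1,HB,40\nS2,HA,35\n")
        m = read_travel_matrix(p, "long", suburb_ids=["S1", "S2"],
                               hospital_ids=["HA", "HB"])
        assert math.isinf(m.minutes[1, 1])
        assert m.minutes[0, 1] == 40

    def test_wide_and_long_encodings_agree(self, tmp_path):
        rng = np.random.default_rng(3)
        minutes = rng.uniform(5, 90, size=(5, 3)).round(2)
        s_ids = [f"S{i}" for i in range(5)]
        h_ids = ["HA", "HB", "HC"]
        wide = "suburb_id," + ",".join(h_ids) + "\n" + "\n".join(
            f"{s}," + ",".join(f"{m:.2f}" for m in row)
            for s, row in zip(s_ids, minutes))
        long = "suburb_id,hospital_id,minutes\n" + "\n".join(
            f"{s},{h},{minutes[i, j]:.2f}"
            for i, s in enumerate(s_ids) for j, h in enumerate(h_ids))
        mw = read_travel_matrix(_write(tmp_path, "w.csv", wide), "wide")
        ml = read_travel_matrix(_write(tmp_path, "l.csv", long), "long",
                                suburb_ids=s_ids, hospital_ids=h_ids)
        np.testing.assert_array_equal(mw.minutes, ml.minutes)

    def test_blank_and_negative_cells_warn(self, tmp_path):
        p = _write(tmp_path, "t.csv", "suburb_id,HA,HB\nS1,,40\nS2,-3,12\n")
        with pytest.warns(UserWarning, match="unreachable"):
            m = read_travel_matrix(p, "wide")
        assert math.isinf(m.minutes[0, 0]) and math.isinf(m.minutes[1, 0])


class TestValidateCity:
    def test_consistent_bundle_is_clean(self, demo_bundle):
        assert validate_city(*demo_bundle) == []

    def test_matrix_missing_suburb_is_named(self, demo_bundle):
        suburbs, hospitals, matrix, incidence = demo_bundle
        report = validate_city(suburbs[:10], hospitals,
                               type(matrix)(matrix.suburb_ids[1:10],
                                            matrix.hospital_ids,
                                            matrix.minutes[1:10]),
                               incidence)
        assert any("missing suburb" in v and "S001" in v for v in report)

    def test_incidence_gap_is_named(self, demo_bundle):
        suburbs, hospitals, matrix, _ = demo_bundle
        gappy = IncidenceTable({AgeBand(0, 64): 0.001, AgeBand(70, None): 0.02})
        report = validate_city(suburbs, hospitals, matrix, gappy)
        assert len(report) == 1 and "gap" in report[0]
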