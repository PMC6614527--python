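"""Domain types and CSV readers/writers for the city bundle.

A *city bundle* is the set of inputs every downstream analysis consumes:

* suburbs — population units with a WGS84 centroid and age-banded headcounts,
* hospitals — candidate ECR (endovascular clot retrieval) hub sites,
* a travel-time matrix (minutes from every suburb centroid to every hospital
  under a named traffic scenario),
* an age-specific annual stroke incidence table.

"Suburb" is used generically for whatever population unit the analysis is run
on (suburbs, postcodes, statistical areas); the pipeline is agnostic.

All coordinates are WGS84 decimal degrees and all spherical computations use
radius 6371 km. File formats are plain CSV; see the reader docstrings for the
exact layouts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for an origin-destination pair with no usable route.
UNREACHABLE = math.inf


# ---------------------------------------------------------------------------
# Age bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class AgeBand:
    """A closed integer age interval, e.g. 65-74, or open-ended (85+).

    ``lower`` and ``upper`` are inclusive years; ``upper is None`` marks an
    open-ended band. ``label`` is the column/row label used in CSV files.
    """

    lower: int
    upper: int | None
    label: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError(f"age band lower bound must be >= 0, got {self.lower}")
        if self.upper is not None and self.upper < self.lower:
            raise ValueError(f"age band {self.lower}-{self.upper} has upper < lower")
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    def default_label(self) -> str:
        return f"{self.lower}+" if self.upper is None else f"{self.lower}-{self.upper}"

    @property
    def open_ended(self) -> bool:
        return self.upper is None

    def width(self, cap: int) -> int:
        """Number of single years covered, closing open bands at age cap-1."""
        hi = cap - 1 if self.upper is None else min(self.upper, cap - 1)
        return max(0, hi - self.lower + 1)

    @classmethod
    def parse(cls, label: str) -> "AgeBand":
        """Parse labels of the form '0-64', '65-74', '85+'."""
        text = label.strip()
        if text.endswith("+"):
            return cls(lower=int(text[:-1]), upper=None, label=text)
        lo, _, hi = text.partition("-")
        if not _:
            raise ValueError(f"cannot parse age band label {label!r}")
        return cls(lower=int(lo), upper=int(hi), label=text)


def check_band_schema(bands: Sequence[AgeBand], *, require_open_end: bool = True) -> None:
    """Validate that bands are sorted, non-overlapping and gapless from 0.

    Raises ValueError naming the first violation.
    """
    if not bands:
        raise ValueError("empty age-band schema")
    ordered = sorted(bands, key=lambda b: b.lower)
    if list(ordered) != list(bands):
        raise ValueError("age bands are not sorted by lower bound")
    if bands[0].lower != 0:
        raise ValueError(f"age-band schema must start at 0, starts at {bands[0].lower}")
    for a, b in zip(bands, bands[1:]):
        if a.open_ended:
            raise ValueError(f"open-ended band {a.label!r} is not last")
        if b.lower != a.upper + 1:
            kind = "overlap" if b.lower <= a.upper else "gap"
            raise ValueError(
                f"age-band schema has a {kind} between {a.label!r} and {b.label!r}"
            )
    if require_open_end and not bands[-1].open_ended:
        raise ValueError("age-band schema must end with an open-ended band (e.g. '85+')")


# ---------------------------------------------------------------------------
# Core records
# ---------------------------------------------------------------------------

def _check_coords(lat: float, lon: float, what: str) -> None:
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
        raise ValueError(f"{what}: invalid coordinates ({lat}, {lon})")


@dataclass
class Suburb:
    """One population unit: centroid plus age-banded headcounts."""

    id: str
    name: str
    lat: float
    lon: float
    population: dict[AgeBand, int]

    def __post_init__(self) -> None:
        _check_coords(self.lat, self.lon, f"suburb {self.id!r}")
        for band, count in self.population.items():
            if count < 0:
                raise ValueError(
                    f"suburb {self.id!r}: negative count {count} in band {band.label!r}"
                )

    @property
    def total_population(self) -> int:
        return sum(self.population.values())


@dataclass
class Hospital:
    """One candidate ECR hub site."""

    id: str
    name: str
    lat: float
    lon: float
    ecr_capable: bool = True

    def __post_init__(self) -> None:
        _check_coords(self.lat, self.lon, f"hospital {self.id!r}")


@dataclass
class IncidenceTable:
    """Annual first-ever stroke rate per person-year, by age band."""

    entries: dict[AgeBand, float]
    source_label: str = ""

    def __post_init__(self) -> None:
        for band, rate in self.entries.items():
            if rate < 0:
                raise ValueError(
                    f"incidence table {self.source_label!r}: negative rate for "
                    f"band {band.label!r}"
                )

    @property
    def bands(self) -> list[AgeBand]:
        return sorted(self.entries, key=lambda b: b.lower)

    def scaled(self, factor: float, label: str | None = None) -> "IncidenceTable":
        return IncidenceTable(
            {b: r * factor for b, r in self.entries.items()},
            source_label=label or f"{self.source_label}*{factor:g}",
        )


@dataclass
class TravelTimeMatrix:
    """Minutes from every suburb centroid to every hospital.

    ``minutes`` is a dense (n_suburbs, n_hospitals) float array; unreachable
    pairs hold ``UNREACHABLE`` (inf).
    """

    suburb_ids: list[str]
    hospital_ids: list[str]
    minutes: np.ndarray
    scenario_label: str = ""

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=float)
        if self.minutes.shape != (len(self.suburb_ids), len(self.hospital_ids)):
            raise ValueError(
                f"matrix shape {self.minutes.shape} does not match "
                f"{len(self.suburb_ids)} suburbs x {len(self.hospital_ids)} hospitals"
            )
        finite = np.isfinite(self.minutes)
        if np.any(self.minutes[finite] < 0):
            raise ValueError("travel-time matrix contains negative finite entries")

    def row(self, suburb_id: str) -> np.ndarray:
        return self.minutes[self.suburb_ids.index(suburb_id)]

    def columns(self, hospital_ids: Sequence[str]) -> np.ndarray:
        idx = [self.hospital_ids.index(h) for h in hospital_ids]
        return self.minutes[:, idx]

    def unreachable_suburbs(self) -> list[str]:
        """Suburbs with no finite time to any hospital."""
        mask = ~np.isfinite(self.minutes).any(axis=1)
        return [s for s, bad in zip(self.suburb_ids, mask) if bad]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_suburbs(path: str | Path, bands: Sequence[AgeBand]) -> list[Suburb]:
    """Read suburbs.csv: ``id,name,lat,lon,<band_1>,...,<band_k>``.

    ``bands`` is the declared age-band schema; every non-coordinate column
    must match a band label exactly (hard error naming any unknown column),
    and every band must be present.
    """
    check_band_schema(bands)
    df = pd.read_csv(path, dtype={"id": str, "name": str})
    required = {"id", "name", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"suburbs file missing columns: {sorted(missing)}")
    by_label = {b.label: b for b in bands}
    extra = [c for c in df.columns if c not in required and c not in by_label]
    if extra:
        raise ValueError(
            f"suburbs file has columns not in the declared age-band schema: {extra}"
        )
    absent = [b.label for b in bands if b.label not in df.columns]
    if absent:
        raise ValueError(f"suburbs file missing age-band columns: {absent}")
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate suburb ids: {sorted(set(dup))}")
    suburbs = []
    for rec in df.to_dict("records"):
        pop = {}
        for label, band in by_label.items():
            count = int(rec[label])
            if count < 0:
                raise ValueError(f"suburb {rec['id']!r}: negative count in band {label!r}")
            pop[band] = count
        suburbs.append(Suburb(id=str(rec["id"]), name=str(rec["name"]),
                              lat=float(rec["lat"]), lon=float(rec["lon"]),
                              population=pop))
    return suburbs


def write_suburbs(suburbs: Sequence[Suburb], path: str | Path) -> None:
    bands = sorted({b for s in suburbs for b in s.population}, key=lambda b: b.lower)
    rows = []
    for s in suburbs:
        row = {"id": s.id, "name": s.name, "lat": s.lat, "lon": s.lon}
        row.update({b.label: s.population.get(b, 0) for b in bands})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_hospitals(path: str | Path) -> list[Hospital]:
    """Read hospitals.csv: ``id,name,lat,lon,ecr_capable``."""
    df = pd.read_csv(path, dtype={"id": str, "name": str})
    missing = {"id", "name", "lat", "lon"} - set(df.columns)
    if missing:
        raise ValueError(f"hospitals file missing columns: {sorted(missing)}")
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate hospital ids: {sorted(set(dup))}")
    out = []
    for rec in df.itertuples(index=False):
        cap = bool(getattr(rec, "ecr_capable", True))
        out.append(Hospital(id=str(rec.id), name=str(rec.name),
                            lat=float(rec.lat), lon=float(rec.lon), ecr_capable=cap))
    return out


def write_hospitals(hospitals: Sequence[Hospital], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": h.id, "name": h.name, "lat": h.lat, "lon": h.lon,
          "ecr_capable": h.ecr_capable} for h in hospitals]
    ).to_csv(path, index=False)


def read_incidence(path: str | Path) -> IncidenceTable:
    """Read incidence.csv: ``band_label,rate_per_person_year,source_label``."""
    df = pd.read_csv(path)
    missing = {"band_label", "rate_per_person_year"} - set(df.columns)
    if missing:
        raise ValueError(f"incidence file missing columns: {sorted(missing)}")
    entries = {
        AgeBand.parse(str(rec.band_label)): float(rec.rate_per_person_year)
        for rec in df.itertuples(index=False)
    }
    source = str(df["source_label"].iloc[0]) if "source_label" in df.columns else ""
    return IncidenceTable(entries=entries, source_label=source)


def write_incidence(table: IncidenceTable, path: str | Path) -> None:
    pd.DataFrame(
        [{"band_label": b.label, "rate_per_person_year": table.entries[b],
          "source_label": table.source_label} for b in table.bands]
    ).to_csv(path, index=False)


def read_travel_matrix(
    path: str | Path,
    layout: str = "wide",
    *,
    suburb_ids: Sequence[str] | None = None,
    hospital_ids: Sequence[str] | None = None,
    scenario_label: str = "",
) -> TravelTimeMatrix:
    """Read a travel-time matrix CSV.

    ``layout='wide'``: one row per suburb, first column ``suburb_id``, one
    column per hospital id. ``layout='long'``: columns
    ``suburb_id,hospital_id,minutes`` (an optional ``scenario_label`` column
    is accepted, as written by the travel cache).

    Blank or negative cells become the unreachable sentinel with a warning.
    If suburb/hospital registries are given, ids outside them are a hard
    error; with a long layout the registries also fix the row/column order
    and absent pairs become unreachable.
    """
    df = pd.read_csv(path, dtype={"suburb_id": str})
    if layout == "wide":
        if "suburb_id" not in df.columns:
            raise ValueError("wide travel matrix needs a 'suburb_id' column")
        s_ids = df["suburb_id"].astype(str).tolist()
        h_ids = [c for c in df.columns if c != "suburb_id"]
        minutes = df[h_ids].to_numpy(dtype=float)
    elif layout == "long":
        need = {"suburb_id", "hospital_id", "minutes"}
        if not need <= set(df.columns):
            raise ValueError(f"long travel matrix needs columns {sorted(need)}")
        df["hospital_id"] = df["hospital_id"].astype(str)
        s_ids = list(suburb_ids) if suburb_ids is not None else sorted(df["suburb_id"].unique())
        h_ids = list(hospital_ids) if hospital_ids is not None else sorted(df["hospital_id"].unique())
        minutes = np.full((len(s_ids), len(h_ids)), UNREACHABLE)
        s_pos = {s: i for i, s in enumerate(s_ids)}
        h_pos = {h: j for j, h in enumerate(h_ids)}
        for rec in df.itertuples(index=False):
            if rec.suburb_id not in s_pos:
                raise ValueError(f"travel matrix references unknown suburb {rec.suburb_id!r}")
            if rec.hospital_id not in h_pos:
                raise ValueError(f"travel matrix references unknown hospital {rec.hospital_id!r}")
            minutes[s_pos[rec.suburb_id], h_pos[rec.hospital_id]] = float(rec.minutes)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")

    if layout == "wide":
        if suburb_ids is not None and (unknown := set(s_ids) - set(suburb_ids)):
            raise ValueError(f"travel matrix references unknown suburbs {sorted(unknown)}")
        if hospital_ids is not None and (unknown := set(h_ids) - set(hospital_ids)):
            raise ValueError(f"travel matrix references unknown hospitals {sorted(unknown)}")

    bad = np.isnan(minutes) | (minutes < 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} blank/negative travel-time cells set to unreachable",
            stacklevel=2,
        )
        minutes[bad] = UNREACHABLE
    return TravelTimeMatrix(list(s_ids), list(h_ids), minutes, scenario_label=scenario_label)


def write_travel_matrix(matrix: TravelTimeMatrix, path: str | Path,
                        layout: str = "wide") -> None:
    """Write a matrix in wide or long layout (minutes to 2 decimals)."""
    if layout == "wide":
        df = pd.DataFrame(matrix.minutes, columns=matrix.hospital_ids)
        df.insert(0, "suburb_id", matrix.suburb_ids)
        df.to_csv(path, index=False, float_format="%.2f")
    elif layout == "long":
        rows = [
            {"suburb_id": s, "hospital_id": h, "minutes": matrix.minutes[i, j],
             "scenario_label": matrix.scenario_label}
            for i, s in enumerate(matrix.suburb_ids)
            for j, h in enumerate(matrix.hospital_ids)
            if np.isfinite(matrix.minutes[i, j])
        ]
        pd.DataFrame(rows, columns=["suburb_id", "hospital_id", "minutes",
                                    "scenario_label"]).to_csv(
            path, index=False, float_format="%.2f")
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


# ---------------------------------------------------------------------------
# Bundle validation
# ---------------------------------------------------------------------------

def validate_city(
    suburbs: Sequence[Suburb],
    hospitals: Sequence[Hospital],
    matrix: TravelTimeMatrix | None = None,
    incidence: IncidenceTable | None = None,
) -> list[str]:
    """Cross-check a city bundle; returns a list of violation messages.

    Never raises: an empty list means the bundle is analysis-ready. Checks id
    uniqueness, matrix/registry agreement, per-suburb reachability and
    incidence-schema gaplessness.
    """
    report: list[str] = []
    s_ids = [s.id for s in suburbs]
    h_ids = [h.id for h in hospitals]
    for name, ids in (("suburb", s_ids), ("hospital", h_ids)):
        seen = set()
        for i in ids:
            if i in seen:
                report.append(f"duplicate {name} id {i!r}")
            seen.add(i)
    if matrix is not None:
        for s in set(s_ids) - set(matrix.suburb_ids):
            report.append(f"travel matrix missing suburb {s!r}")
        for s in set(matrix.suburb_ids) - set(s_ids):
            report.append(f"travel matrix has unknown suburb {s!r}")
        for h in set(h_ids) - set(matrix.hospital_ids):
            report.append(f"travel matrix missing hospital {h!r}")
        for h in set(matrix.hospital_ids) - set(h_ids):
            report.append(f"travel matrix has unknown hospital {h!r}")
        for s in matrix.unreachable_suburbs():
            report.append(f"suburb {s!r} has no finite travel time to any hospital")
    if incidence is not None:
        try:
            check_band_schema(incidence.bands)
        except ValueError as e:
            report.append(f"incidence bands: {e}")
    pop_bands: set[AgeBand] = set()
    for s in suburbs:
        pop_bands.update(s.population)
    if pop_bands:
        try:
            check_band_schema(sorted(pop_bands, key=lambda b: b.lower))
        except ValueError as e:
            report.append(f"population bands: {e}")
    return report
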