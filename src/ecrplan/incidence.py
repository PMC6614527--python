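"""Stroke-count projection from age-banded populations and incidence rates.

Expected annual strokes per suburb = sum over age bands of
population(band) x annual first-ever stroke rate(band). Census population
bands and the bands of published incidence studies rarely coincide, so rates
are first harmonized onto the population schema by overlap-length weighting.
The projection is a deterministic expectation — no sampling.

Caseload for a hub model then restricts the projection to suburbs covered
within the travel-time threshold and applies an ECR eligibility fraction
(default 0.15: roughly 15% of strokes are large-vessel occlusions suitable
for clot retrieval) to obtain the average annual interventional caseload
per hub.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._util import round_half_up
from .catchment import CatchmentModel, CoverageReport
from .city_model import AgeBand, IncidenceTable, Suburb, check_band_schema

DEFAULT_ELIGIBILITY = 0.15

#: Age at which open-ended bands are closed for overlap weighting; rates are
#: assumed constant within a band, so only relative year counts matter.
OPEN_BAND_CAP = 100


@dataclass
class StrokeProjection:
    """Expected annual strokes per suburb, plus the city total."""

    per_suburb: dict[str, float]
    source_label: str

    @property
    def city_total(self) -> float:
        return sum(self.per_suburb.values())


@dataclass
class HubCaseload:
    hub_id: str
    covered_strokes: float
    eligible_cases: float


@dataclass
class CaseloadReport:
    """Projected ECR caseload for one hub model.

    ``per_hub_average`` is the headline planning number: total eligible
    cases divided by the number of hubs, rounded half-up to a whole
    patient count.
    """

    hub_ids: list[str]
    per_hub: list[HubCaseload]
    eligibility_fraction: float
    source_label: str

    @property
    def total_covered_strokes(self) -> float:
        return sum(h.covered_strokes for h in self.per_hub)

    @property
    def total_eligible_cases(self) -> float:
        return sum(h.eligible_cases for h in self.per_hub)

    @property
    def per_hub_average(self) -> int:
        return average_caseload_per_hub(self.total_covered_strokes,
                                        self.eligibility_fraction,
                                        len(self.hub_ids))


def harmonize_bands(population_bands: Sequence[AgeBand],
                    incidence: IncidenceTable,
                    cap: int = OPEN_BAND_CAP) -> dict[AgeBand, float]:
    """Re-express incidence rates on the population band schema.

    The rate for a population band is the overlap-length-weighted mean of
    the incidence rates over the single years it spans (equivalently: give
    every year of age the rate of its incidence band, then average within
    the population band). Open-ended bands are closed at ``cap`` years for
    weighting. Both schemas must be gapless from age 0; a gap is a hard
    error.
    """
    check_band_schema(list(population_bands))
    check_band_schema(incidence.bands)
    year_rate = [0.0] * cap
    for band in incidence.bands:
        hi = cap - 1 if band.upper is None else min(band.upper, cap - 1)
        for y in range(band.lower, hi + 1):
            year_rate[y] = incidence.entries[band]
    out: dict[AgeBand, float] = {}
    for band in population_bands:
        hi = cap - 1 if band.upper is None else min(band.upper, cap - 1)
        years = range(band.lower, hi + 1)
        n = len(years)
        if n == 0:
            raise ValueError(f"population band {band.label!r} lies above the "
                             f"open-band cap of {cap} years")
        out[band] = sum(year_rate[y] for y in years) / n
    return out


def project_strokes(suburbs: Sequence[Suburb],
                    incidence: IncidenceTable) -> StrokeProjection:
    """Expected annual strokes per suburb and in total.

    Rates are harmonized onto each suburb's band schema, then multiplied by
    the banded headcounts and summed. Invariant to any hub choice.
    """
    per_suburb: dict[str, float] = {}
    rate_cache: dict[tuple[AgeBand, ...], dict[AgeBand, float]] = {}
    for s in suburbs:
        bands = tuple(sorted(s.population, key=lambda b: b.lower))
        if bands not in rate_cache:
            rate_cache[bands] = harmonize_bands(bands, incidence)
        rates = rate_cache[bands]
        per_suburb[s.id] = sum(count * rates[band]
                               for band, count in s.population.items())
    return StrokeProjection(per_suburb=per_suburb,
                            source_label=incidence.source_label)


def average_caseload_per_hub(total_covered_strokes: float,
                             eligibility: float, k: int) -> int:
    """round_half_up(total strokes x eligibility / k) — whole patients."""
    if not (0.0 <= eligibility <= 1.0):
        raise ValueError(f"eligibility fraction {eligibility} outside [0, 1]")
    if k < 1:
        raise ValueError("need at least one hub")
    return round_half_up(total_covered_strokes * eligibility / k)


def caseload(model: CatchmentModel, cov: CoverageReport,
             projection: StrokeProjection,
             eligibility: float = DEFAULT_ELIGIBILITY) -> CaseloadReport:
    """Projected strokes and ECR-eligible cases per hub, covered suburbs only.

    A suburb contributes to its assigned hub's caseload only if its travel
    time is within the coverage threshold ("population at risk serviced
    within the threshold").
    """
    if not (0.0 <= eligibility <= 1.0):
        raise ValueError(f"eligibility fraction {eligibility} outside [0, 1]")
    missing = set(model.assignment) - set(projection.per_suburb)
    if missing:
        raise ValueError(f"projection missing suburbs: {sorted(missing)[:5]}")
    per_hub = []
    for h in model.hub_ids:
        strokes = sum(
            projection.per_suburb[s]
            for s in model.catchment(h)
            if model.assigned_minutes[s] < cov.threshold_minutes
        )
        per_hub.append(HubCaseload(hub_id=h, covered_strokes=strokes,
                                   eligible_cases=strokes * eligibility))
    return CaseloadReport(hub_ids=list(model.hub_ids), per_hub=per_hub,
                          eligibility_fraction=eligibility,
                          source_label=projection.source_label)


def sum_model_patients(per_hub_counts: Sequence[float]) -> float:
    """Total patients serviced by a model: plain sum of per-hub counts.

    Used to validate the row totals of published per-hub caseload tables.
    """
    counts = list(per_hub_counts)
    if any(c < 0 for c in counts):
        raise ValueError("per-hub counts must be non-negative")
    return sum(counts)
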