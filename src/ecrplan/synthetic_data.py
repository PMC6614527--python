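"""Synthetic city generation with known ground truth.

Two generators:

* :func:`generate_city` — a statistically plausible metropolitan city:
  suburb centroids uniform over a disc, log-normal suburb populations split
  into age bands by fixed proportions (largest-remainder integer rounding),
  hospitals at k-means centres of the centroid cloud, and a travel matrix
  from the synthetic peak-hour travel model. Defaults emulate the setting
  the pipeline was designed for: ~226 population units, 5 candidate hubs.

* :func:`generate_known_coverage_city` — a fixture generator that plants
  travel times directly (not via distance) so each hub's catchment attains
  an exact requested covered fraction at the 30-minute threshold; used for
  end-to-end recovery tests where the right answer must be known a priori.

Both are fully deterministic per seed. The shipped incidence tables are
synthetic illustrative rates shaped like published Australian age-specific
first-ever stroke incidence (steeply increasing with age), not the actual
study rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from ._util import round1, round_half_up
from .catchment import DEFAULT_THRESHOLD_MIN
from .city_model import (AgeBand, Hospital, IncidenceTable, Suburb,
                         TravelTimeMatrix, check_band_schema)
from .travel_time import (SyntheticTravelProvider, TravelScenario,
                          build_matrix)

#: Census-style age bands used by the default generator.
DEFAULT_BANDS = (
    AgeBand(0, 44), AgeBand(45, 54), AgeBand(55, 64),
    AgeBand(65, 74), AgeBand(75, 84), AgeBand(85, None),
)

#: Age-structure proportions for a metropolitan Australian-style population.
DEFAULT_AGE_PROPORTIONS = (0.60, 0.13, 0.11, 0.09, 0.05, 0.02)

#: Synthetic illustrative annual first-ever stroke rates per person-year.
#: Shaped like published Australian incidence (roughly doubling per decade
#: after midlife); the labels make clear these are not real study rates.
SYNTHETIC_INCIDENCE_HIGH = IncidenceTable(
    {AgeBand(0, 44): 0.0001, AgeBand(45, 54): 0.0015, AgeBand(55, 64): 0.0030,
     AgeBand(65, 74): 0.0080, AgeBand(75, 84): 0.0180, AgeBand(85, None): 0.0280},
    source_label="synthetic_high",
)
SYNTHETIC_INCIDENCE_LOW = SYNTHETIC_INCIDENCE_HIGH.scaled(
    0.58, label="synthetic_low")


@dataclass
class CityGenSpec:
    """Parameters of the statistical city generator.

    Defaults mirror the target setting: 226 suburbs, 5 candidate hubs, a
    ~60 km-diameter urban disc, median suburb population ~12k with
    log-normal spread, morning-peak travel.
    """

    n_suburbs: int = 226
    n_hospitals: int = 5
    seed: int = 0
    extent_km: float = 60.0
    center_lat: float = -33.87
    center_lon: float = 151.0
    pop_log_mean: float = math.log(12_000.0)
    pop_log_sd: float = 0.6
    bands: tuple[AgeBand, ...] = DEFAULT_BANDS
    age_proportions: tuple[float, ...] = DEFAULT_AGE_PROPORTIONS
    scenario: TravelScenario = field(
        default_factory=lambda: TravelScenario(
            label="morning_peak", base_speed_kmh=40.0,
            congestion_multiplier=1.5, noise_sd_min=3.0))

    def __post_init__(self) -> None:
        if not (self.n_suburbs >= self.n_hospitals >= 1):
            raise ValueError("need n_suburbs >= n_hospitals >= 1")
        if len(self.bands) != len(self.age_proportions):
            raise ValueError("bands and age_proportions length mismatch")
        if abs(sum(self.age_proportions) - 1.0) > 1e-9:
            raise ValueError("age proportions must sum to 1")
        check_band_schema(list(self.bands))


def largest_remainder_split(total: int, proportions: Sequence[float]) -> list[int]:
    """Split an integer total by proportions; parts sum to total exactly.

    Each part gets its floor share; leftover units go to the largest
    fractional remainders (ties by position for determinism).
    """
    quotas = [total * p for p in proportions]
    parts = [int(math.floor(q)) for q in quotas]
    leftover = total - sum(parts)
    order = sorted(range(len(quotas)),
                   key=lambda i: (-(quotas[i] - parts[i]), i))
    for i in order[:leftover]:
        parts[i] += 1
    return parts


def _offset_latlon(lat0: float, lon0: float, dx_km: float,
                   dy_km: float) -> tuple[float, float]:
    # Local tangent-plane approximation; adequate at metropolitan scale.
    lat = lat0 + dy_km / 111.195
    lon = lon0 + dx_km / (111.195 * math.cos(math.radians(lat0)))
    return lat, lon


def generate_city(
    spec: CityGenSpec,
) -> tuple[list[Suburb], list[Hospital], TravelTimeMatrix, IncidenceTable]:
    """Generate a complete synthetic city bundle, deterministic per seed.

    Centroids are uniform over a disc of diameter ``extent_km``; populations
    are log-normal, split into bands by largest remainder; hospitals sit at
    seeded k-means centres of the centroid cloud (so candidate sites track
    population geography, as real hospitals do); the travel matrix comes
    from the synthetic peak-hour provider. The bundle passes
    :func:`ecrplan.city_model.validate_city` by construction.
    """
    rng = np.random.default_rng(spec.seed % (2 ** 31))
    radius = spec.extent_km / 2.0
    r = radius * np.sqrt(rng.uniform(size=spec.n_suburbs))
    theta = rng.uniform(0, 2 * math.pi, size=spec.n_suburbs)
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    totals = np.maximum(
        1, np.round(rng.lognormal(spec.pop_log_mean, spec.pop_log_sd,
                                  size=spec.n_suburbs))).astype(int)
    suburbs = []
    for i in range(spec.n_suburbs):
        lat, lon = _offset_latlon(spec.center_lat, spec.center_lon,
                                  xy[i, 0], xy[i, 1])
        parts = largest_remainder_split(int(totals[i]), spec.age_proportions)
        suburbs.append(Suburb(
            id=f"S{i + 1:03d}", name=f"Suburb {i + 1}", lat=lat, lon=lon,
            population=dict(zip(spec.bands, parts))))

    km = KMeans(n_clusters=spec.n_hospitals, n_init=10,
                random_state=spec.seed % (2 ** 31)).fit(xy)
    # Order centres west-to-east so hospital ids are stable per seed.
    centres = km.cluster_centers_[np.lexsort((km.cluster_centers_[:, 1],
                                              km.cluster_centers_[:, 0]))]
    hospitals = []
    for j, (dx, dy) in enumerate(centres):
        lat, lon = _offset_latlon(spec.center_lat, spec.center_lon, dx, dy)
        hospitals.append(Hospital(id=f"H{j + 1}", name=f"Hospital {j + 1}",
                                  lat=lat, lon=lon, ecr_capable=True))

    provider = SyntheticTravelProvider()
    matrix = build_matrix(suburbs, hospitals, provider, spec.scenario)
    return suburbs, hospitals, matrix, SYNTHETIC_INCIDENCE_HIGH


def generate_known_coverage_city(
    targets: Sequence[tuple[float, int]],
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD_MIN,
) -> tuple[list[Suburb], list[Hospital], TravelTimeMatrix, IncidenceTable]:
    """Build a bundle whose per-hub coverage is planted exactly.

    ``targets`` is one (covered_fraction, catchment_size) pair per hub.
    Travel times are constructed directly: suburbs in hub j's catchment get
    a time well under the threshold (covered) or well over it (uncovered)
    to hub j, and times to every other hub exceed their time to hub j, so
    the nearest-hub assignment reproduces the intended catchments and each
    hub covers exactly round_half_up(fraction x size) suburbs.

    A (fraction, size) pair is infeasible — hard error — when no integer
    covered count displays as that fraction at one-decimal-percent
    precision (e.g. 50% of 1 suburb).
    """
    if not targets:
        raise ValueError("need at least one (fraction, size) target")
    rng = np.random.default_rng(seed % (2 ** 31))
    covered_counts = []
    for frac, size in targets:
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"coverage fraction {frac} outside [0, 1]")
        if size < 1:
            raise ValueError(f"catchment size {size} must be >= 1")
        covered = round_half_up(frac * size)
        if round1(100.0 * covered / size) != round1(100.0 * frac):
            raise ValueError(
                f"target fraction {frac} infeasible for catchment of {size}: "
                f"nearest achievable is {covered}/{size}")
        covered_counts.append(covered)

    n_suburbs = sum(size for _, size in targets)
    n_hubs = len(targets)
    suburbs = []
    hospitals = [Hospital(id=f"H{j + 1}", name=f"Planted hub {j + 1}",
                          lat=-33.8 + 0.05 * j, lon=151.0 + 0.05 * j)
                 for j in range(n_hubs)]
    minutes = np.full((n_suburbs, n_hubs), 0.0)
    i = 0
    for j, ((_, size), covered) in enumerate(zip(targets, covered_counts)):
        for m in range(size):
            lat, lon = _offset_latlon(-33.8, 151.0,
                                      float(rng.uniform(-30, 30)),
                                      float(rng.uniform(-30, 30)))
            total = int(rng.integers(2_000, 30_000))
            parts = largest_remainder_split(total, DEFAULT_AGE_PROPORTIONS)
            suburbs.append(Suburb(
                id=f"S{i + 1:03d}", name=f"Planted suburb {i + 1}",
                lat=lat, lon=lon,
                population=dict(zip(DEFAULT_BANDS, parts))))
            own = (threshold * float(rng.uniform(0.2, 0.8)) if m < covered
                   else threshold * float(rng.uniform(1.2, 2.0)))
            minutes[i, :] = own + threshold * float(rng.uniform(1.5, 3.0))
            minutes[i, j] = own
            i += 1
    matrix = TravelTimeMatrix([s.id for s in suburbs],
                              [h.id for h in hospitals], minutes,
                              scenario_label=f"planted_seed{seed}")
    return suburbs, hospitals, matrix, SYNTHETIC_INCIDENCE_HIGH
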