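"""Travel-time providers: a provider contract plus a synthetic peak-hour model.

Real deployments of this kind of analysis query a commercial directions API
for drive times from each suburb centroid to each candidate hub under
morning-peak traffic. Such APIs are rate-limited (historically ~2500 free
queries per day) and not reproducible — the same query returns different
minutes on different days. This module therefore defines:

* ``TravelProvider`` — the minimal per-pair contract any adapter (live API or
  otherwise) must satisfy, with a per-session request quota;
* ``SyntheticTravelProvider`` — a fully deterministic stand-in that converts
  great-circle distance to peak-hour minutes via a detour factor, a base
  road speed, a congestion multiplier and truncated Gaussian noise;
* ``TravelCache``/``build_matrix`` — a resumable origin-destination cache so
  re-runs issue zero new provider calls and quota-limited providers are
  chunked across sessions.

No network code exists anywhere in the package; the live adapter is a
contract only.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .city_model import Hospital, Suburb, TravelTimeMatrix, UNREACHABLE, _check_coords

EARTH_RADIUS_KM = 6371.0

#: Ratio of road distance to great-circle distance; 1.2-1.4 is typical for
#: metropolitan road networks, 1.3 is the model default.
DEFAULT_DETOUR_FACTOR = 1.3


@dataclass(frozen=True)
class TravelScenario:
    """Named traffic scenario for the synthetic travel model.

    Parameters
    ----------
    label:
        Scenario name recorded in matrices and cache files
        (e.g. ``"morning_peak"``).
    base_speed_kmh:
        Free-flow road speed in km/h.
    congestion_multiplier:
        Factor >= 1 applied to free-flow time; peak-hour congestion.
    noise_sd_min:
        Standard deviation (minutes) of per-pair Gaussian noise, truncated
        at zero. 0 gives the deterministic distance-only model.
    seed:
        Seed for the noise; part of the scenario so a matrix is a
        reproducible artifact.
    detour_factor:
        Road-to-crow-flies distance ratio.
    bias_min:
        Optional additive offset in minutes (e.g. to emulate a systematic
        ambulance-vs-API difference); default 0.
    """

    label: str = "morning_peak"
    base_speed_kmh: float = 40.0
    congestion_multiplier: float = 1.5
    noise_sd_min: float = 0.0
    seed: int = 0
    detour_factor: float = DEFAULT_DETOUR_FACTOR
    bias_min: float = 0.0

    def __post_init__(self) -> None:
        if self.base_speed_kmh <= 0:
            raise ValueError("base_speed_kmh must be positive")
        if self.congestion_multiplier < 1:
            raise ValueError("congestion_multiplier must be >= 1")
        if self.noise_sd_min < 0:
            raise ValueError("noise_sd_min must be >= 0")


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points, R=6371 km."""
    _check_coords(a[0], a[1], "haversine origin")
    _check_coords(b[0], b[1], "haversine destination")
    lat1, lon1, lat2, lon2 = map(np.radians, (a[0], a[1], b[0], b[1]))
    s = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(s)))


def _pair_rng(origin: tuple[float, float], dest: tuple[float, float],
              seed: int) -> np.random.Generator:
    # Stable per-(origin, dest, seed) stream: hash the packed coordinates so
    # two calls for the same pair always draw the same noise.
    digest = hashlib.blake2b(
        struct.pack("<4d", origin[0], origin[1], dest[0], dest[1]),
        digest_size=8,
    ).digest()
    pair_key = int.from_bytes(digest, "little") % (2 ** 32)
    return np.random.default_rng(np.random.SeedSequence([seed % (2 ** 31), pair_key]))


def synth_travel_minutes(origin: tuple[float, float], dest: tuple[float, float],
                         scenario: TravelScenario) -> float:
    """Synthetic peak-hour drive time in minutes.

    minutes = (haversine_km * detour_factor / base_speed_kmh) * 60
              * congestion_multiplier + bias + N(0, noise_sd_min), truncated
    at 0. Deterministic per (origin, dest, scenario.seed).
    """
    km = haversine_km(origin, dest)
    minutes = (km * scenario.detour_factor / scenario.base_speed_kmh) * 60.0
    minutes *= scenario.congestion_multiplier
    minutes += scenario.bias_min
    if scenario.noise_sd_min > 0:
        rng = _pair_rng(origin, dest, scenario.seed)
        minutes += float(rng.normal(0.0, scenario.noise_sd_min))
    return max(0.0, minutes)


class TravelProvider(Protocol):
    """Per-pair travel-time source.

    ``travel_minutes`` returns minutes, or ``UNREACHABLE``/raises for a pair
    with no route. ``session_limit`` is the maximum number of requests the
    backing service accepts per session (2500 mirrors historical free-tier
    directions-API quotas); callers must chunk work accordingly.
    """

    session_limit: int

    def travel_minutes(self, origin: tuple[float, float],
                       dest: tuple[float, float],
                       scenario: TravelScenario) -> float: ...


@dataclass
class SyntheticTravelProvider:
    """Deterministic provider backed by :func:`synth_travel_minutes`.

    Counts requests per session so quota behaviour is testable;
    ``start_session`` resets the per-session counter (a real adapter would do
    this once per day).
    """

    session_limit: int = 2500
    calls_this_session: int = 0
    total_calls: int = 0

    def start_session(self) -> None:
        self.calls_this_session = 0

    def travel_minutes(self, origin: tuple[float, float],
                       dest: tuple[float, float],
                       scenario: TravelScenario) -> float:
        if self.calls_this_session >= self.session_limit:
            raise RuntimeError(
                f"provider session quota of {self.session_limit} requests exhausted"
            )
        self.calls_this_session += 1
        self.total_calls += 1
        return synth_travel_minutes(origin, dest, scenario)


class TravelCache:
    """Resumable origin-destination cache keyed by (suburb, hospital, scenario).

    Persists as the long travel CSV layout plus a ``scenario_label`` column,
    so a cache file is also a readable travel matrix.
    """

    def __init__(self, path: str | Path | None = None) -> None:
        self.path = Path(path) if path is not None else None
        self._store: dict[tuple[str, str, str], float] = {}
        if self.path is not None and self.path.exists():
            df = pd.read_csv(self.path, dtype={"suburb_id": str, "hospital_id": str})
            for rec in df.itertuples(index=False):
                key = (rec.suburb_id, rec.hospital_id, str(rec.scenario_label))
                self._store[key] = float(rec.minutes)

    def __len__(self) -> int:
        return len(self._store)

    def get(self, suburb_id: str, hospital_id: str, scenario_label: str) -> float | None:
        return self._store.get((suburb_id, hospital_id, scenario_label))

    def put(self, suburb_id: str, hospital_id: str, scenario_label: str,
            minutes: float) -> None:
        self._store[(suburb_id, hospital_id, scenario_label)] = minutes

    def flush(self) -> None:
        if self.path is None:
            return
        rows = [
            {"suburb_id": s, "hospital_id": h, "minutes": m, "scenario_label": lab}
            for (s, h, lab), m in sorted(self._store.items())
        ]
        pd.DataFrame(rows, columns=["suburb_id", "hospital_id", "minutes",
                                    "scenario_label"]).to_csv(self.path, index=False)


def build_matrix(
    suburbs: Sequence[Suburb],
    hospitals: Sequence[Hospital],
    provider: TravelProvider,
    scenario: TravelScenario,
    cache: TravelCache | None = None,
) -> TravelTimeMatrix:
    """Build the complete suburb x hospital travel-time matrix.

    Cached pairs are never re-requested, so a warm re-run issues zero
    provider calls. Uncached pairs are requested in chunks of the provider's
    session quota (``start_session`` is called between chunks when the
    provider supports it). A provider failure on a pair yields the
    unreachable sentinel with a warning rather than aborting the build.
    """
    if not suburbs or not hospitals:
        raise ValueError("build_matrix needs non-empty suburb and hospital registries")
    cache = cache if cache is not None else TravelCache()
    minutes = np.empty((len(suburbs), len(hospitals)))
    pending: list[tuple[int, int]] = []
    for i, s in enumerate(suburbs):
        for j, h in enumerate(hospitals):
            hit = cache.get(s.id, h.id, scenario.label)
            if hit is None:
                pending.append((i, j))
            else:
                minutes[i, j] = hit

    import warnings

    limit = getattr(provider, "session_limit", None) or len(pending) or 1
    for chunk_start in range(0, len(pending), limit):
        if chunk_start > 0 and hasattr(provider, "start_session"):
            provider.start_session()
        for i, j in pending[chunk_start:chunk_start + limit]:
            s, h = suburbs[i], hospitals[j]
            try:
                m = provider.travel_minutes((s.lat, s.lon), (h.lat, h.lon), scenario)
            except Exception as exc:  # provider failure is per-pair, not fatal
                warnings.warn(f"provider failed for ({s.id}, {h.id}): {exc}",
                              stacklevel=2)
                m = UNREACHABLE
            minutes[i, j] = m
            cache.put(s.id, h.id, scenario.label, m)
    cache.flush()
    return TravelTimeMatrix([s.id for s in suburbs], [h.id for h in hospitals],
                            minutes, scenario_label=scenario.label)
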