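"""Suburb-to-hub assignment and within-threshold coverage statistics.

A catchment model assigns every suburb to the hub (among a chosen subset)
with the minimum travel time — the "logical comparison of traveling time"
step of hub planning. Coverage then counts, per hub, the suburbs whose
assigned travel time is strictly below a threshold (default 30 minutes, the
idealized maximum onset-to-hub drive time used in ECR service design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import round1, round_half_up
from .city_model import TravelTimeMatrix

DEFAULT_THRESHOLD_MIN = 30.0


@dataclass
class CatchmentModel:
    """A hub subset plus the suburb partition it induces.

    ``assignment`` maps each reachable suburb to its nearest hub;
    ``assigned_minutes`` holds the attained minimum. Suburbs with no finite
    time to any selected hub are listed in ``unassignable`` and excluded
    from the partition.
    """

    hub_ids: list[str]
    assignment: dict[str, str]
    assigned_minutes: dict[str, float]
    unassignable: list[str] = field(default_factory=list)

    def catchment(self, hub_id: str) -> list[str]:
        return [s for s, h in self.assignment.items() if h == hub_id]

    @property
    def n_assigned(self) -> int:
        return len(self.assignment)


@dataclass
class HubCoverage:
    """Per-hub coverage: catchment size and within-threshold count/percent."""

    hub_id: str
    catchment_count: int
    covered_count: int

    @property
    def covered_pct(self) -> float:
        """Percent of catchment suburbs covered, 1 decimal, half-up."""
        if self.catchment_count == 0:
            return 0.0
        return round1(100.0 * self.covered_count / self.catchment_count)


@dataclass
class CoverageReport:
    """Coverage of a catchment model at one threshold.

    Totals are integer counts of suburbs; percentages are display values
    only and are never summed.
    """

    per_hub: list[HubCoverage]
    threshold_minutes: float
    total_suburbs: int

    @property
    def total_covered_suburbs(self) -> int:
        return sum(h.covered_count for h in self.per_hub)

    def covered_suburb_ids(self, model: CatchmentModel) -> list[str]:
        return [s for s, m in model.assigned_minutes.items()
                if m < self.threshold_minutes]


def assign(matrix: TravelTimeMatrix, hub_ids: Sequence[str]) -> CatchmentModel:
    """Assign every suburb to its minimum-travel-time hub among ``hub_ids``.

    Ties are broken by hub order in ``hub_ids`` (first wins). Suburbs
    unreachable from every selected hub are reported as unassignable with a
    warning.
    """
    hub_ids = list(hub_ids)
    if not hub_ids:
        raise ValueError("hub_ids must be non-empty")
    unknown = [h for h in hub_ids if h not in matrix.hospital_ids]
    if unknown:
        raise ValueError(f"unknown hub ids: {unknown}")
    sub = matrix.columns(hub_ids)  # (n_suburbs, n_hubs) in hub_ids order
    assignment: dict[str, str] = {}
    minutes: dict[str, float] = {}
    unassignable: list[str] = []
    for i, s in enumerate(matrix.suburb_ids):
        row = sub[i]
        if not np.isfinite(row).any():
            unassignable.append(s)
            continue
        j = int(np.nanargmin(np.where(np.isfinite(row), row, np.inf)))
        assignment[s] = hub_ids[j]
        minutes[s] = float(row[j])
    if unassignable:
        warnings.warn(
            f"{len(unassignable)} suburbs unreachable from all selected hubs "
            f"and excluded from the partition", stacklevel=2)
    return CatchmentModel(hub_ids=hub_ids, assignment=assignment,
                          assigned_minutes=minutes, unassignable=unassignable)


def coverage(model: CatchmentModel,
             threshold: float = DEFAULT_THRESHOLD_MIN) -> CoverageReport:
    """Count per-hub suburbs with assigned minutes strictly below threshold.

    The comparison is strict (< threshold): a suburb at exactly the
    threshold is not covered.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    per_hub = []
    for h in model.hub_ids:
        members = model.catchment(h)
        covered = sum(1 for s in members if model.assigned_minutes[s] < threshold)
        per_hub.append(HubCoverage(hub_id=h, catchment_count=len(members),
                                   covered_count=covered))
    return CoverageReport(per_hub=per_hub, threshold_minutes=threshold,
                          total_suburbs=model.n_assigned)


def reconstruct_total_from_row(
    per_hub: Sequence[tuple[float, int]]) -> int:
    """Reconstruct a published table's total from per-hub (percent, count).

    Published coverage tables print, per hub, the covered percentage (1
    decimal) and the catchment size, plus a total covered-suburb count. The
    total is reconstructed as sum over hubs of round_half_up(pct/100 * count)
    — the arithmetic under which internally consistent printed rows validate.
    """
    total = 0
    for pct, count in per_hub:
        if not (0.0 <= pct <= 100.0):
            raise ValueError(f"percentage {pct} outside [0, 100]")
        if count < 0:
            raise ValueError(f"negative catchment count {count}")
        total += round_half_up(pct / 100.0 * count)
    return total
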