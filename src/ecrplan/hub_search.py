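"""Exhaustive hub-combination enumeration, scoring and ranking.

The planning question is: what is the minimum number of hubs, and which
combination, that adequately covers the city? With a handful of candidate
sites the subset space is tiny (C(5, k) at most 10 here), so every
combination is scored exhaustively — no greedy or integer-programming
machinery is warranted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .catchment import CoverageReport


@dataclass
class ModelScore:
    """Score of one hub subset at a fixed threshold and incidence source."""

    hub_ids: tuple[str, ...]
    total_covered_suburbs: int
    total_covered_population_at_risk: float = 0.0
    threshold_minutes: float = 30.0
    incidence_source: str = ""
    coverage_report: CoverageReport | None = None

    @property
    def k(self) -> int:
        return len(self.hub_ids)


def enumerate_models(candidate_ids: Sequence[str], k_min: int,
                     k_max: int) -> list[tuple[str, ...]]:
    """All hub subsets of size k_min..k_max, in lexicographic candidate order.

    Returns exactly C(n, k) subsets for each k, deterministically ordered.
    """
    candidates = list(candidate_ids)
    if not candidates:
        raise ValueError("candidate_ids must be non-empty")
    if not (1 <= k_min <= k_max <= len(candidates)):
        raise ValueError(
            f"need 1 <= k_min <= k_max <= {len(candidates)}, "
            f"got k_min={k_min}, k_max={k_max}")
    out: list[tuple[str, ...]] = []
    for k in range(k_min, k_max + 1):
        out.extend(combinations(candidates, k))
    return out


def rank_models(scores: Sequence[ModelScore]) -> list[ModelScore]:
    """Rank scores best-first.

    Descending total covered suburbs, ties by descending covered population
    at risk, then ascending hub-id tuple for determinism. All scores must
    share one threshold and one incidence source; mixing is a hard error
    because the totals would not be comparable.
    """
    if not scores:
        return []
    thresholds = {s.threshold_minutes for s in scores}
    if len(thresholds) > 1:
        raise ValueError(f"cannot rank across thresholds: {sorted(thresholds)}")
    sources = {s.incidence_source for s in scores}
    if len(sources) > 1:
        raise ValueError(f"cannot rank across incidence sources: {sorted(sources)}")
    return sorted(
        scores,
        key=lambda s: (-s.total_covered_suburbs,
                       -s.total_covered_population_at_risk, s.hub_ids),
    )


def marginal_gain(scores: Sequence[ModelScore]) -> dict[int, dict]:
    """Best total per subset size k, and the gain from adding one hub.

    Returns {k: {"best": ModelScore, "gain_from_prev": int | None,
    "improves": bool | None}} where ``improves`` says whether the best
    (k)-model strictly beats the best (k-1)-model on covered suburbs —
    the "is one more hub worth it?" question.
    """
    ks = sorted({s.k for s in scores})
    if len(ks) < 2:
        raise ValueError("marginal_gain needs scores spanning >= 2 subset sizes")
    best: dict[int, ModelScore] = {}
    for k in ks:
        best[k] = rank_models([s for s in scores if s.k == k])[0]
    out: dict[int, dict] = {}
    prev_k = None
    for k in ks:
        if prev_k is None:
            out[k] = {"best": best[k], "gain_from_prev": None, "improves": None}
        else:
            gain = best[k].total_covered_suburbs - best[prev_k].total_covered_suburbs
            out[k] = {"best": best[k], "gain_from_prev": gain, "improves": gain > 0}
        prev_k = k
    return out
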