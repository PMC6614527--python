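# Methods

## Problem and scope

`ecrplan` implements maximal-coverage hub selection for a time-critical
hospital service (endovascular clot retrieval, ECR) by exhaustive
enumeration. The decision variables are which k of n candidate hospitals to
designate as hubs; the objective observed is the number of population units
whose peak-hour travel time to their nearest selected hub is below a
threshold, with projected stroke counts as a secondary, population-weighted
view. With n ≤ ~15 candidates exhaustive enumeration is exact and cheap
(C(5, 3..5) = 16 subsets in the reference setting), so no greedy heuristic
or integer program is used, and none is provided.

Out of scope by design: live directions-API querying (the provider is a
contract only), road-network routing, capacity-constrained or second-nearest
assignment, drip-and-ship vs mothership transport modelling, and any
workforce/rostering analysis.

## Catchment and coverage rules

- Assignment is nearest-hub by travel time; ties are broken by the order of
  hubs in the requested subset (first wins). The tie rule is arbitrary but
  deterministic; with continuous travel times ties are measure-zero.
- Coverage is a **strict** comparison, minutes < threshold: a suburb at
  exactly 30.0 minutes is not covered. The boundary case is tested.
- Suburbs with no finite time to any selected hub are excluded from the
  partition (and the coverage denominator) with a warning.
- Per-hub percentages are display values, rounded to one decimal with
  half-up rounding; totals are always integer counts of suburbs, never sums
  of rounded percentages. Published tables of this kind are only internally
  consistent under count arithmetic, which is why
  `reconstruct_total_from_row` uses sum of round_half_up(pct/100 × count).

## Incidence projection

Expected annual strokes per suburb = Σ over age bands of headcount × annual
first-ever stroke rate. This is a deterministic expectation; no sampling.
Census bands and incidence-study bands rarely coincide, so rates are
harmonized onto the population schema first: each single year of age
inherits the rate of its incidence band, and a population band's rate is
the mean over the years it spans (equivalently, an overlap-length-weighted
mean of band rates). Open-ended bands are closed at a cap of 100 years for
weighting only; because rates are constant within bands, the cap affects
only the relative weight of the terminal band and any choice ≥ the last
band boundary gives identical results when open-ended bands align, which is
the recommended usage. Both schemas must be gapless from age 0 — a gap is a
hard error rather than a silent zero rate.

The shipped incidence tables (`synthetic_high`, `synthetic_low`) are
illustrative synthetic rates shaped like published Australian age-specific
incidence — ~1e-4/person-year below 45, roughly doubling per decade to
2.8e-2 at 85+, with the low table a 0.58-scaled variant mimicking the
spread between source studies. They are clearly labelled synthetic and are
not the rates of any particular study; users supply their own
`incidence.csv` for real analyses.

Caseload: per-hub covered strokes are summed over suburbs assigned to the
hub *and* covered within the threshold ("population at risk serviced");
multiplying by an ECR eligibility fraction (default 0.15, the commonly used
share of strokes suitable for clot retrieval) and dividing by k gives the
average annual per-hub caseload, rounded half-up to whole patients.
Reference arithmetic: 9292 × 0.15 / 3 = 464.6 → 465. The corresponding
4-hub value is 9991 × 0.15 / 4 = 374.66 → 375 under this (or any standard)
rounding rule.

## Synthetic travel model

minutes = haversine_km × detour / speed × 60 × congestion + bias + noise,
truncated at zero, with defaults detour 1.3 (typical road-network
circuity), base speed 40 km/h, congestion multiplier 1.5 (morning peak),
bias 0 (an optional additive offset is exposed because ambulance-vs-API
comparisons report small systematic differences, ~3.5 min), and Gaussian
noise with SD 3 min in the generator's default scenario. Noise is drawn
from a stream keyed by (origin, destination, scenario seed) via a hash of
the packed coordinates, so any pair's time is reproducible regardless of
evaluation order. Distances use the sphere of radius 6371 km; the paper-of-
record CRS question does not arise because only centroids are used.

The provider contract carries a per-session request quota (default 2500,
mirroring historical free-tier directions-API limits); `build_matrix`
chunks uncached pairs to the quota and persists a resumable long-format CSV
cache, so a warm re-run issues zero requests and total requests across
sessions equal the number of uncached pairs.

## Synthetic city generator

Defaults model the target setting: 226 suburbs, 5 candidate hubs, a 60 km
urban disc, log-normal suburb populations (median 12 000, σ_log 0.6 —
metropolitan suburb-scale heterogeneity), and a fixed age structure
(60/13/11/9/5/2% across 0–44/45–54/55–64/65–74/75–84/85+), split per suburb
by largest-remainder rounding so band counts sum exactly to each suburb's
total. Hospitals are placed at seeded k-means centres of the centroid cloud
so candidate sites track population geography, as real hospitals do.
Everything is deterministic per seed.

What the generator does **not** emulate: real road networks and anisotropic
congestion, coastline/river geography, spatially correlated age structure
(older coastal suburbs etc.), and suburb size heterogeneity by area.
Passing tests on generated cities therefore demonstrate the correctness of
the assignment/coverage/projection machinery and the internal consistency
of the pipeline, not that any particular real city needs k hubs.

A second generator plants travel times directly (not via distance) so each
hub's catchment attains an exactly requested covered fraction at the
threshold; it is the fixture for end-to-end recovery tests where the right
answer must be known in advance. A target fraction is rejected as
infeasible when no integer covered count displays as that fraction at
one-decimal-percent precision.

## Reference tables

The package ships the published Sydney coverage and per-hub caseload tables
(five candidate hubs: RPA, LPH, WH, POW, RNS; 226 suburbs; 30-minute
threshold). Because the underlying travel times and census inputs are not
distributed, these support validation of the aggregation arithmetic — row
sums, total reconstruction from per-hub (percent, count) pairs, ranking —
not re-derivation of the percentages. Two printed coverage rows
("3 hospitals-8", "4 hospitals-5") disagree with their own per-hub columns
and one coverage-table patients total ("5 hospitals-1") disagrees with the
self-consistent caseload-table row sum; `ecrplan.datasets` flags these, and
no rounding rule was tuned to force agreement.

## Numerical choices and sizes

- Unreachable travel times are `inf`; blank/negative CSV cells coerce to it
  with a warning.
- Half-up rounding everywhere a published-style integer or one-decimal
  value is produced (`_util.round_half_up`/`round1`); Python's banker's
  rounding is never used for display values.
- Ranking tie-break: covered suburbs ↓, covered population at risk ↓,
  hub-id tuple ↑ — total and deterministic.
- Test and acceptance problem sizes (random 50×5 instances, 20-seed sweeps
  of 40-suburb cities, one 226-suburb full analysis) were chosen as the
  smallest sizes that exercise every code path and the combinatorial
  properties; the whole suite runs in a few seconds.

## Limitations

Centroid-to-hospital times ignore within-suburb travel variation; the
coverage statistic counts suburbs, not people, so small and large suburbs
weigh equally (the population-at-risk ranking key partially compensates);
incidence projection assumes rates constant within bands and stationary
over time; and the synthetic travel model's noise is independent across
pairs, unlike spatially correlated real congestion.
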