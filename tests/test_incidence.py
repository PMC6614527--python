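import numpy as np
import pytest

from ecrplan import (AgeBand, IncidenceTable, Suburb, TravelTimeMatrix,
                     assign, average_caseload_per_hub, caseload, coverage,
                     harmonize_bands, project_strokes, sum_model_patients)


def random_band_schema(rng, max_age=100):
    """Random gapless schema over [0, open) for the year-by-year oracle."""
    cuts = sorted(rng.choice(np.arange(1, max_age), size=rng.integers(1, 6),
                             replace=False))
    bounds = [0, *cuts]
    bands = [AgeBand(lo, hi - 1) for lo, hi in zip(bounds, bounds[1:])]
    bands.append(AgeBand(bounds[-1], None))
    return bands


class TestHarmonize:
    def test_identity_when_schemas_match(self):
        bands = [AgeBand(0, 64), AgeBand(65, None)]
        table = IncidenceTable({bands[0]: 0.002, bands[1]: 0.015})
        rates = harmonize_bands(bands, table)
        assert rates[bands[0]] == pytest.approx(0.002)
        assert rates[bands[1]] == pytest.approx(0.015)

    def test_weighted_mean_over_split_band(self):
        # population band 0-69 spans 65 years at r1 and 5 years at r2
        r1, r2 = 0.001, 0.008
        table = IncidenceTable({AgeBand(0, 64): r1, AgeBand(65, 69): r2,
                                AgeBand(70, None): 0.02})
        pop = [AgeBand(0, 69), AgeBand(70, None)]
        rates = harmonize_bands(pop, table)
        assert rates[pop[0]] == pytest.approx((65 * r1 + 5 * r2) / 70)

    def test_matches_year_by_year_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            pop_bands = random_band_schema(rng)
            inc_bands = random_band_schema(rng)
            table = IncidenceTable(
                {b: float(rng.uniform(0, 0.03)) for b in inc_bands})
            rates = harmonize_bands(pop_bands, table, cap=100)
            # oracle: every single year of age carries its band's rate
            year_rate = np.zeros(100)
            for b in inc_bands:
                hi = 99 if b.upper is None else b.upper
                year_rate[b.lower:hi + 1] = table.entries[b]
            for b in pop_bands:
                hi = 99 if b.upper is None else b.upper
                assert rates[b] == pytest.approx(year_rate[b.lower:hi + 1].mean())

    def test_gap_in_schema_is_hard_error(self):
        table = IncidenceTable({AgeBand(0, 64): 0.001, AgeBand(70, None): 0.02})
        with pytest.raises(ValueError, match="gap"):
            harmonize_bands([AgeBand(0, None)], table)


def _one_suburb(pop_by_band):
    return Suburb(id="S1", name="only", lat=-33.9, lon=151.0,
                  population=pop_by_band)


class TestProjection:
    def test_hand_computed_expectation(self):
        bands = [AgeBand(0, 64), AgeBand(65, None)]
        table = IncidenceTable({bands[0]: 0.002, bands[1]: 0.010})
        s = _one_suburb({bands[0]: 1000, bands[1]: 500})
        proj = project_strokes([s], table)
        assert proj.per_suburb["S1"] == pytest.approx(7.0)
        assert proj.city_total == pytest.approx(7.0)

    def test_zero_population_zero_strokes(self):
        bands = [AgeBand(0, 64), AgeBand(65, None)]
        table = IncidenceTable({b: 0.01 for b in bands})
        proj = project_strokes([_one_suburb({b: 0 for b in bands})], table)
        assert proj.city_total == 0.0

    def test_linear_in_rates(self, small_city):
        suburbs, _, _, table = small_city
        doubled = table.scaled(2.0)
        a = project_strokes(suburbs, table)
        b = project_strokes(suburbs, doubled)
        assert b.city_total == pytest.approx(2 * a.city_total)
        for s in a.per_suburb:
            assert b.per_suburb[s] == pytest.approx(2 * a.per_suburb[s])


class TestCaseload:
    def test_published_three_hub_arithmetic(self):
        # 9292 covered strokes, 15% eligible, 3 hubs -> 465 per hub per year
        assert average_caseload_per_hub(9292, 0.15, 3) == 465

    def test_zero_eligibility_means_zero_cases(self, small_city):
        suburbs, hospitals, matrix, table = small_city
        model = assign(matrix, [h.id for h in hospitals])
        rep = coverage(model, 30)
        cl = caseload(model, rep, project_strokes(suburbs, table), 0.0)
        assert cl.total_eligible_cases == 0.0 and cl.per_hub_average == 0

    def test_per_hub_sums_match_brute_force(self, small_city):
        suburbs, hospitals, matrix, table = small_city
        model = assign(matrix, [h.id for h in hospitals])
        rep = coverage(model, 30)
        proj = project_strokes(suburbs, table)
        cl = caseload(model, rep, proj)
        for hub in cl.per_hub:
            expected = sum(
                proj.per_suburb[s.id] for s in suburbs
                if model.assignment.get(s.id) == hub.hub_id
                and model.assigned_minutes[s.id] < 30)
            assert hub.covered_strokes == pytest.approx(expected)
            assert hub.eligible_cases == pytest.approx(0.15 * expected)

    def test_conservation_at_infinite_threshold(self, small_city):
        """With no time limit every stroke lands in exactly one catchment."""
        suburbs, hospitals, matrix, table = small_city
        proj = project_strokes(suburbs, table)
        import itertools
        ids = [h.id for h in hospitals]
        for k in (1, 2, 4):
            for hubs in itertools.combinations(ids, k):
                model = assign(matrix, hubs)
                rep = coverage(model, 1e9)
                cl = caseload(model, rep, proj)
                assert cl.total_covered_strokes == pytest.approx(proj.city_total)

    def test_eligibility_out_of_range_rejected(self, small_city):
        suburbs, hospitals, matrix, table = small_city
        model = assign(matrix, [hospitals[0].id])
        rep = coverage(model, 30)
        with pytest.raises(ValueError, match="eligibility"):
            caseload(model, rep, project_strokes(suburbs, table), 1.5)


class TestSumModelPatients:
    @pytest.mark.parametrize("counts, expected", [
        ([2837, 2270, 4185], 9292),
        ([1647, 1332, 2433], 5412),
        ([], 0),
    ])
    def test_row_totals(self, counts, expected):
        assert sum_model_patients(counts) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sum_model_patients([5, -1])
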