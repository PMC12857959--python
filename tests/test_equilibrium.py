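import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from krillspr.biology import FleetPars, LifeHistory, ParameterError, base_krill
from krillspr.equilibrium import (
    DegenerateCompositionError,
    LengthGrid,
    build_gtg,
    edge_survival,
    equilibrium_numbers,
    equilibrium_state,
    expected_catch_composition,
    spr,
)
from krillspr.validation import age_structured_catch_density, age_structured_spr


class TestLengthGrid:
    def test_uniform_spacing_enforced(self):
        with pytest.raises(ParameterError):
            LengthGrid([0.0, 2.0, 5.0], bin_width=2.0)

    def test_for_life_history_covers_largest_group(self, base_lh):
        grid = LengthGrid.for_life_history(base_lh)
        gtg = build_gtg(base_lh)
        assert grid.edges[-1] >= gtg.linfs.max()
        assert grid.bin_width == 2.0
        assert grid.lower_edges[0] == 0.0


class TestGrowthTypeGroups:
    def test_zero_cv_collapses_to_single_group(self, base_lh):
        lh = LifeHistory(linf=60, cv_linf=0.0, mk=1.0)
        gtg = build_gtg(lh, n_gtg=13)
        assert gtg.n_gtg == 1
        assert gtg.linfs[0] == 60.0 and gtg.weights[0] == 1.0

    def test_stated_spacing_rule(self):
        # linf 60, cv 0.1, 13 groups, truncation 2.5 SD -> extremes 45 and 75
        lh = LifeHistory(linf=60, cv_linf=0.1, mk=1.0)
        gtg = build_gtg(lh, n_gtg=13, truncation=2.5)
        assert gtg.linfs[6] == pytest.approx(60.0)
        assert gtg.linfs[0] == pytest.approx(45.0)
        assert gtg.linfs[-1] == pytest.approx(75.0)
        assert np.allclose(np.diff(gtg.linfs), gtg.linfs[1] - gtg.linfs[0])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        cv=st.floats(0.0, 0.12),
        n=st.integers(0, 10).map(lambda i: 2 * i + 1),
    )
    def test_weights_normalised_and_symmetric(self, cv, n):
        lh = LifeHistory(linf=60, cv_linf=cv, mk=0.9)
        gtg = build_gtg(lh, n_gtg=n)
        assert gtg.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (gtg.weights >= 0).all()
        assert np.allclose(gtg.linfs + gtg.linfs[::-1], 2 * 60.0)

    def test_even_group_count_rejected(self, base_lh):
        with pytest.raises(ParameterError):
            build_gtg(base_lh, n_gtg=12)


class TestEquilibriumNumbers:
    def test_survival_collapses_analytically_without_fishing(self):
        # single group, mk=1, fm=0: survivorship to edge L is (linf-L)/linf
        lh = LifeHistory(linf=60, cv_linf=0.0, mk=1.0)
        grid = LengthGrid.for_life_history(lh)
        gtg = build_gtg(lh, 1)
        surv = edge_survival(lh, FleetPars(38, 45, 0.0), grid, gtg)
        i30 = int(np.flatnonzero(np.isclose(grid.edges, 30.0))[0])
        assert surv[0, i30] / surv[0, 0] == pytest.approx(0.5, rel=1e-12)
        # and matches a direct per-bin recursion at every edge
        n_direct = [1.0]
        for lo, up in zip(grid.lower_edges, grid.upper_edges):
            ratio = max((60.0 - up) / (60.0 - lo), 0.0) if lo < 60.0 else 0.0
            n_direct.append(n_direct[-1] * ratio)
        assert np.allclose(surv[0], n_direct)

    def test_unfished_survival_ignores_selectivity(self, base_lh):
        grid = LengthGrid.for_life_history(base_lh)
        gtg = build_gtg(base_lh)
        a = equilibrium_numbers(base_lh, FleetPars(38, 45, 0.0), grid, gtg)
        b = equilibrium_numbers(base_lh, FleetPars(20, 30, 0.0), grid, gtg)
        assert np.array_equal(a, b)

    def test_numbers_non_increasing_and_zero_beyond_group_linf(
        self, base_lh, base_fleet
    ):
        grid = LengthGrid.for_life_history(base_lh)
        gtg = build_gtg(base_lh)
        numbers = equilibrium_numbers(base_lh, base_fleet, grid, gtg)
        assert (np.diff(numbers, axis=1) <= 1e-15).all()
        for g in range(gtg.n_gtg):
            beyond = grid.lower_edges >= gtg.linfs[g]
            assert (numbers[g, beyond] == 0).all()


class TestCatchComposition:
    def test_normalised(self, base_lh, base_fleet):
        state = equilibrium_state(base_lh, base_fleet)
        assert state.catch_props.sum() == pytest.approx(1.0, abs=1e-9)
        assert (state.catch_props >= 0).all()

    def test_fully_selected_catch_mirrors_population(self, base_lh):
        # selectivity saturates to exactly 1 over the whole support
        fleet = FleetPars(1e-6, 2e-6, 1.0)
        grid = LengthGrid.for_life_history(base_lh)
        gtg = build_gtg(base_lh)
        numbers = equilibrium_numbers(base_lh, fleet, grid, gtg)
        catch = expected_catch_composition(numbers, fleet, grid)
        pop = numbers.sum(axis=0) / numbers.sum()
        assert np.allclose(catch, pop, atol=1e-9)

    def test_selectivity_above_all_lengths_is_degenerate(self, base_lh):
        fleet = FleetPars(5000.0, 5010.0, 1.0)
        grid = LengthGrid.for_life_history(base_lh)
        gtg = build_gtg(base_lh)
        numbers = equilibrium_numbers(base_lh, fleet, grid, gtg)
        with pytest.raises(DegenerateCompositionError):
            expected_catch_composition(numbers, fleet, grid)

    def test_modal_bin_matches_age_structured_simulator(self, base_lh, base_fleet):
        state = equilibrium_state(base_lh, base_fleet)
        oracle = age_structured_catch_density(base_lh, base_fleet)
        model_mode = state.grid.lower_edges[np.argmax(state.catch_props)]
        oracle_mode = 2.0 * np.argmax(oracle)
        assert model_mode == oracle_mode


class TestSPR:
    @pytest.mark.parametrize(
        "lh",
        [
            base_krill(),
            LifeHistory(linf=55, cv_linf=0.05, mk=1.5, l50_mat=30, l95_mat=36),
            LifeHistory(linf=65, cv_linf=0.0, mk=0.5, l50_mat=40, l95_mat=50),
        ],
    )
    def test_unexploited_spr_is_exactly_one(self, lh):
        assert spr(lh, FleetPars(38, 45, 0.0)) == 1.0

    def test_nonspawning_limit(self, base_lh):
        # selectivity entirely below maturity, extreme pressure -> SPR ~ 0
        assert spr(base_lh, FleetPars(25, 30, 100.0)) < 1e-4

    def test_monotone_in_fishing_pressure(self, base_lh):
        vals = [spr(base_lh, FleetPars(38, 45, fm)) for fm in np.linspace(0, 10, 50)]
        assert (np.diff(vals) <= 1e-12).all()

    def test_monotone_decreasing_in_assumed_linf(self, base_fleet):
        # data-free evaluations with fixed absolute selectivity
        vals = [
            spr(base_krill(linf=v), base_fleet) for v in np.arange(55.0, 66.0)
        ]
        assert (np.diff(vals) < 0).all()

    def test_fixed_fleet_spr_increases_with_growth_coefficient(self, base_fleet):
        # data-free direction: larger k (smaller M/K) -> less length-specific
        # depletion at fixed F/M -> higher SPR.  The headline low-k-high-SPR
        # pattern arises from re-fitting, covered in the sensitivity tests.
        vals = [spr(base_krill().with_k(k), base_fleet) for k in (0.2, 0.7, 1.2)]
        assert vals[0] < vals[1] < vals[2]

    def test_grid_refinement_stability(self, base_lh, base_fleet):
        coarse = spr(base_lh, base_fleet)
        fine = spr(
            base_lh, base_fleet, grid=LengthGrid.for_life_history(base_lh, 1.0)
        )
        assert abs(coarse - fine) / fine < 0.005

    def test_agrees_with_age_structured_oracle(self, base_lh, base_fleet):
        a = spr(base_lh, base_fleet)
        b = age_structured_spr(base_lh, base_fleet)
        assert abs(a - b) / b < 0.02
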