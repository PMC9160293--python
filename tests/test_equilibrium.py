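"""Wild and GM-perturbed equilibria, calibration and critical rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from aedesgm.equilibrium import (
    ATTRACTOR,
    NON_ADMISSIBLE,
    SADDLE,
    TotalPopulationState,
    basic_offspring_number,
    calibrate_carrying_capacities,
    carrying_capacity_from_aquatic,
    classify_equilibria,
    critical_release_rate,
    domain_critical_release,
    expected_equilibrium_curve,
    gm_cubic_roots,
    integrate_ode,
    ode_rhs,
    wild_equilibrium,
    _b_coeff,
)
from aedesgm.maps import map_from_matrix, with_capacities


def _residual_scale(params, state):
    return max(1.0, max(abs(v) for v in state.as_array()))


class TestBasicOffspringNumber:
    def test_zero_capacity(self, params):
        assert basic_offspring_number(params, 0.0) == 0.0

    def test_printed_house_value_unit_area(self, params):
        # unit-area evaluation of the literature house capacity
        assert basic_offspring_number(params, 3.6876) == pytest.approx(
            303.0, rel=1e-3)

    def test_area_consistent_cell_value(self, params):
        # on a 25 m² cell the encounter coefficient is diluted by the area
        q = basic_offspring_number(params, 3.6876, area=25.0)
        assert q == pytest.approx(
            basic_offspring_number(params, 3.6876) / 25.0, rel=1e-12)

    def test_linearity_in_K(self, params):
        assert basic_offspring_number(params, 7.0) == pytest.approx(
            2.0 * basic_offspring_number(params, 3.5), rel=1e-12)


class TestWildEquilibrium:
    def test_borderline_offspring_number_gives_half_capacity(self, params):
        b = _b_coeff(params, 1.0)
        K = 4.0 * b  # exactly Q0 = 1
        eqs = wild_equilibrium(params, K)
        assert eqs.Q0 == pytest.approx(1.0, rel=1e-12)
        assert eqs.wild.aquatic == pytest.approx(K / 2.0, rel=1e-9)

    def test_subcritical_population_has_only_trivial_equilibrium(self, params):
        b = _b_coeff(params, 1.0)
        eqs = wild_equilibrium(params, 2.0 * b)  # Q0 = 0.5
        assert eqs.Q0 == pytest.approx(0.5, rel=1e-12)
        assert eqs.admissible_aquatic == ()
        assert eqs.equilibria[0].state == TotalPopulationState(0, 0, 0, 0, 0)

    @pytest.mark.parametrize("K,area", [(3.6876, 25.0), (0.7375, 25.0),
                                        (1.0, 1.0), (40.0, 100.0)])
    def test_equilibrium_is_stationary(self, params, K, area):
        eqs = wild_equilibrium(params, K, area)
        for eq in eqs.equilibria:
            rhs = ode_rhs(params, eq.state, K, 0.0, area)
            assert np.abs(rhs).max() <= 1e-10 * _residual_scale(params, eq.state)

    def test_general_sex_ratio_forms(self):
        # F*/M* follow r and the respective mortalities, not the printed
        # r = 1/2 specialization
        from aedesgm.parameters import ModelParameters
        p = ModelParameters(r=0.3, mu_m=0.2)
        eqs = wild_equilibrium(p, 5.0)
        top = eqs.wild.state
        assert top.F == pytest.approx(p.r * p.eta_a * top.A / p.mu_f, rel=1e-12)
        assert top.M == pytest.approx(
            (1 - p.r) * p.eta_a * top.A / p.mu_m, rel=1e-12)


class TestCarryingCapacityInversion:
    def test_round_trip_over_K_grid(self, params):
        for K in np.geomspace(0.05, 50.0, 12):
            eqs = wild_equilibrium(params, K, area=25.0)
            if eqs.wild is None:
                continue
            back = carrying_capacity_from_aquatic(params, eqs.wild.aquatic,
                                                  area=25.0)
            assert back == pytest.approx(K, rel=1e-9)

    def test_small_population_limit(self, params):
        b = _b_coeff(params, 1.0)
        K = carrying_capacity_from_aquatic(params, b * 1.001)
        # K -> 0 requires A -> 0, but the inversion floor is A > b:
        # approaching it from above blows K up instead
        assert K > 100 * b
        tiny = carrying_capacity_from_aquatic(params, 2.0 * b)
        assert tiny == pytest.approx(4.0 * b, rel=1e-9)  # the Q0 = 1 point

    def test_degenerate_denominator_is_error(self, params):
        b = _b_coeff(params, 1.0)
        with pytest.raises(ValueError):
            carrying_capacity_from_aquatic(params, b)
        with pytest.raises(ValueError):
            carrying_capacity_from_aquatic(params, 0.5 * b)


class TestCalibration:
    def test_reference_map_capacities(self, params, reference_grid):
        # frozen from the calibration itself; the literature prints
        # 3.6876 / 0.7375 for the same construction
        assert reference_grid.K_house == pytest.approx(3.6815, abs=2e-4)
        assert reference_grid.K_street == pytest.approx(0.73630, abs=4e-5)
        assert reference_grid.K_house / reference_grid.K_street == \
            pytest.approx(5.0, rel=1e-12)

    def test_female_total_round_trip(self, params, reference_grid):
        from aedesgm.scenarios import domain_female_equilibrium
        total = domain_female_equilibrium(params, reference_grid)
        assert total == pytest.approx(10000.0, rel=1e-6)

    def test_monotone_in_target(self, params, reference_grid):
        K_pairs = [calibrate_carrying_capacities(params, reference_grid, F)
                   for F in (5000.0, 10000.0, 20000.0)]
        houses = [k[0] for k in K_pairs]
        streets = [k[1] for k in K_pairs]
        assert houses == sorted(houses) and streets == sorted(streets)
        assert houses[0] < houses[1] < houses[2]

    def test_infeasible_target_names_range(self, params, reference_grid):
        with pytest.raises(ValueError, match="feasible range"):
            calibrate_carrying_capacities(params, reference_grid, 1e-6)

    def test_street_weight_convention(self, params, reference_grid):
        # discounting the street term forces larger capacities
        K_plain, _ = calibrate_carrying_capacities(params, reference_grid,
                                                   10000.0)
        K_weighted, _ = calibrate_carrying_capacities(
            params, reference_grid, 10000.0, street_weight=0.2)
        assert K_weighted > K_plain


class TestGMRoots:
    def test_zero_release_factors_into_wild_quadratic(self, params):
        K = 3.6876
        cubic = gm_cubic_roots(params, K, 0.0, area=25.0)
        wild = wild_equilibrium(params, K, area=25.0)
        assert sorted(cubic.admissible_aquatic) == pytest.approx(
            sorted(wild.admissible_aquatic), rel=1e-9)

    def test_below_critical_two_admissible_roots(self, params):
        K = 3.6815
        Lc = critical_release_rate(params, K, area=25.0)
        eqs = gm_cubic_roots(params, K, 0.5 * Lc, area=25.0)
        assert eqs.phi < 0
        assert len(eqs.admissible_aquatic) == 2
        aquatics = [eq.aquatic for eq in eqs.equilibria]
        assert min(aquatics) < 0  # the third root is negative

    def test_above_critical_no_admissible_roots(self, params):
        K = 3.6815
        Lc = critical_release_rate(params, K, area=25.0)
        eqs = gm_cubic_roots(params, K, 1.5 * Lc, area=25.0)
        assert eqs.phi > 0
        assert eqs.admissible_aquatic == ()

    def test_roots_are_stationary(self, params):
        K, area = 3.6815, 25.0
        L = 0.4 * critical_release_rate(params, K, area)
        eqs = gm_cubic_roots(params, K, L, area)
        for eq in eqs.equilibria:
            if not eq.admissible:
                continue
            rhs = ode_rhs(params, eq.state, K, L, area)
            assert np.abs(rhs).max() <= 1e-9 * _residual_scale(params, eq.state)

    @settings(deadline=None, max_examples=60)
    @given(K=st.floats(0.2, 50.0),
           Lfrac=st.one_of(st.just(0.0), st.floats(0.05, 0.9),
                           st.floats(1.1, 3.0)),
           area=st.sampled_from([1.0, 25.0]))
    def test_cardano_matches_companion_matrix(self, params, K, Lfrac, area):
        b = _b_coeff(params, area)
        if K <= 3.0 * b:
            return
        L = Lfrac * critical_release_rate(params, K, area)
        eqs = gm_cubic_roots(params, K, L, area)
        got = sorted(eq.aquatic for eq in eqs.equilibria[1:])
        companion = np.roots([1.0, -K, eqs.b * K, eqs.b * eqs.c * K])
        expected = sorted(
            x.real for x in companion
            if abs(x.imag) <= 1e-9 * (1.0 + abs(x))
            and (L > 0.0 or abs(x.real) > 1e-9 * max(1.0, K)))
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g == pytest.approx(e, rel=1e-9, abs=1e-9 * max(1.0, K))


class TestStability:
    def test_gm_branch_labels(self, params):
        K, area = 3.6815, 25.0
        L = 0.5 * critical_release_rate(params, K, area)
        eqs = classify_equilibria(params, K, L,
                                  gm_cubic_roots(params, K, L, area), area)
        admissible = [e for e in eqs.equilibria if e.admissible and e.aquatic > 0]
        admissible.sort(key=lambda e: e.aquatic)
        assert admissible[-1].stability == ATTRACTOR
        assert admissible[0].stability == SADDLE
        negative = [e for e in eqs.equilibria if not e.admissible]
        assert all(e.stability == NON_ADMISSIBLE for e in negative)

    def test_trivial_equilibrium_attracts_without_release(self, params):
        eqs = classify_equilibria(params, 3.6815, 0.0,
                                  wild_equilibrium(params, 3.6815, 25.0), 25.0)
        assert eqs.equilibria[0].stability == ATTRACTOR

    def test_labels_agree_with_forward_integration(self, params):
        K, area = 3.6815, 25.0
        L = 0.5 * critical_release_rate(params, K, area)
        eqs = classify_equilibria(params, K, L,
                                  gm_cubic_roots(params, K, L, area), area)
        for eq in eqs.equilibria:
            if not eq.admissible or eq.aquatic == 0.0:
                continue
            nudged = eq.state.as_array() * (1.0 + 1e-3)
            nudged[4] = eq.state.G  # G is pinned by the release rate
            _, traj = integrate_ode(params, nudged, K, L,
                                    horizon=600.0, dt=5.0, area=area)
            stays = abs(traj[-1, 1] - eq.aquatic) < 0.05 * max(1.0, eq.aquatic)
            assert stays == (eq.stability == ATTRACTOR)


class TestIntegrateODE:
    def test_wild_equilibrium_is_invariant(self, params):
        K, area = 3.6815, 25.0
        top = wild_equilibrium(params, K, area).wild.state
        _, traj = integrate_ode(params, top, K, 0.0, horizon=300.0, dt=5.0,
                                area=area)
        drift = np.abs(traj - top.as_array()).max(axis=0)
        assert (drift <= 1e-3 * np.maximum(1.0, np.abs(top.as_array()))).all()

    def test_saddle_shoulders_toward_attractor(self, params):
        K, area = 3.6815, 25.0
        L = 0.5 * critical_release_rate(params, K, area)
        eqs = gm_cubic_roots(params, K, L, area)
        low, high = sorted(eqs.admissible_aquatic)
        from aedesgm.equilibrium import _companions
        start = _companions(params, low * 1.05, K, L, area)
        _, traj = integrate_ode(params, start, K, L, horizon=2000.0, dt=10.0,
                                area=area)
        assert traj[-1, 1] == pytest.approx(high, rel=5e-3)

    def test_supercritical_release_collapses(self, params):
        K, area = 3.6815, 25.0
        L = 1.2 * critical_release_rate(params, K, area)
        start = wild_equilibrium(params, K, area).wild.state
        _, traj = integrate_ode(params, start, K, L, horizon=3000.0, dt=10.0,
                                area=area)
        assert traj[-1, 1] < 1e-6 * start.A  # aquatic collapse
        assert traj[-1, 4] == pytest.approx(L / params.mu_g, rel=1e-6)


class TestCriticalRates:
    @pytest.mark.parametrize("K", [0.7363, 3.6815])
    def test_discriminant_vanishes_at_critical_rate(self, params, K):
        area = 25.0
        Lc = critical_release_rate(params, K, area)
        phi = gm_cubic_roots(params, K, Lc, area).phi
        scale = max(1.0, K**6)
        assert abs(phi) <= 1e-8 * scale

    def test_monotone_in_capacity(self, params):
        area = 25.0
        Ks = np.linspace(0.7363, 3.6815, 25)
        Ls = [critical_release_rate(params, K, area) for K in Ks]
        assert all(b > a for a, b in zip(Ls, Ls[1:]))

    def test_matches_bisection_on_discriminant(self, params):
        K, area = 3.6815, 25.0
        Lc = critical_release_rate(params, K, area)

        def phi_of_L(L):
            return gm_cubic_roots(params, K, L, area).phi

        bracket = brentq(phi_of_L, 0.5 * Lc, 2.0 * Lc, xtol=1e-12, rtol=1e-12)
        assert Lc == pytest.approx(bracket, rel=1e-8)

    def test_small_capacity_rejected(self, params):
        b = _b_coeff(params, 1.0)
        with pytest.raises(ValueError, match="3b"):
            critical_release_rate(params, 2.0 * b)

    def test_domain_rate_degenerate_and_bounded(self, params, reference_grid):
        all_house = map_from_matrix(np.ones((4, 4)), dx=5, dy=5)
        all_house = with_capacities(all_house, reference_grid.K_house,
                                    reference_grid.K_house)
        Lcrit = domain_critical_release(params, all_house)
        assert Lcrit == pytest.approx(
            critical_release_rate(params, all_house.K_house, 25.0), rel=1e-12)
        Lc_s = critical_release_rate(params, reference_grid.K_street, 25.0)
        Lc_h = critical_release_rate(params, reference_grid.K_house, 25.0)
        mixed = domain_critical_release(params, reference_grid)
        assert Lc_s < mixed < Lc_h


class TestExpectedCurve:
    def test_zero_release_reduces_to_wild_sum(self, params, reference_grid):
        curve = expected_equilibrium_curve(params, reference_grid, [0.0])
        wild_h = wild_equilibrium(params, reference_grid.K_house, 25.0).wild
        wild_s = wild_equilibrium(params, reference_grid.K_street, 25.0).wild
        total = 1072 * wild_h.aquatic + 528 * wild_s.aquatic
        assert curve[0] == pytest.approx(total, rel=1e-12)
        assert curve[0] == pytest.approx(4206.6, abs=0.1)

    def test_vanishes_beyond_house_critical_rate(self, params, reference_grid):
        Lc_h = critical_release_rate(params, reference_grid.K_house, 25.0)
        curve = expected_equilibrium_curve(params, reference_grid,
                                           [1.01 * Lc_h, 2.0 * Lc_h])
        assert (curve == 0.0).all()

    def test_non_increasing(self, params, reference_grid):
        L_grid = np.linspace(0.0, 40.0, 60)
        curve = expected_equilibrium_curve(params, reference_grid, L_grid)
        assert (np.diff(curve) <= 1e-9).all()


class TestPropositionDichotomy:
    @settings(deadline=None, max_examples=40)
    @given(beta=st.floats(5.0, 80.0), eta=st.floats(0.1, 1.0),
           muf=st.floats(0.05, 0.5), K=st.floats(1e-3, 10.0))
    def test_nontrivial_equilibrium_iff_offspring_number_at_least_one(
            self, beta, eta, muf, K):
        from aedesgm.parameters import ModelParameters
        p = ModelParameters(beta=beta, eta_a=eta, mu_f=muf)
        eqs = wild_equilibrium(p, K)
        if eqs.Q0 >= 1.0:
            assert len(eqs.admissible_aquatic) >= 1
        else:
            assert eqs.admissible_aquatic == ()
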