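"""Mass-action cycle kinetics: derivatives, conservation, equilibria."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.special import comb

import girkflow.kinetics as kin
from girkflow import (
    SPECIES,
    StimulusProtocol,
    basal_equilibrium,
    conserved_sums,
    derivatives,
    girk_occupancy_closed_form,
    initial_state,
    simulate,
    state_vector,
    steady_state,
    sweep_k12,
)


class TestDerivatives:
    def test_rest_state_no_stimulus(self, gi_params, geometry):
        """At the naive initial state with k12 = 0, the only active flux is
        trimer dissociation: d(RT)/dt = 0, d(T)/dt = −k54·T."""
        y0 = initial_state(geometry)
        dy = derivatives(y0, gi_params, k12_now=0.0)
        d = dict(zip(SPECIES, dy))
        assert d["RT"] == 0.0
        assert d["T"] == pytest.approx(-0.002 * 100.0, rel=1e-12)

    def test_stimulated_complex_formation(self, gi_params, geometry):
        """With k12 switched on, d(RT)/dt = k12·R*·T ≈ 1.04e3 µm⁻² s⁻¹."""
        y0 = initial_state(geometry)
        dy = derivatives(y0, gi_params, k12_now=0.2075)
        d = dict(zip(SPECIES, dy))
        assert d["RT"] == pytest.approx(0.2075 * 50.0 * 100.0, rel=1e-12)

    @given(
        values=st.lists(st.floats(0.0, 200.0), min_size=11, max_size=11),
        k12=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_conservation_built_into_scheme(self, gi_params, values, k12):
        """Receptor, Gα, Gβγ and GIRK derivative sums vanish algebraically
        for any non-negative state."""
        y = np.array(values)
        dy = derivatives(y, gi_params, k12)
        sums = conserved_sums(dy)[0]
        scale = max(np.abs(dy).max(), 1.0)
        assert np.all(np.abs(sums) <= 1e-9 * scale)

    def test_negative_state_rejected(self, gi_params):
        y = state_vector(R_star=-1.0)
        with pytest.raises(kin.InvalidStateError):
            derivatives(y, gi_params, 0.1)


class TestOccupancyClosedForm:
    def test_no_ligand(self, gi_params):
        occ = girk_occupancy_closed_form(0.0, gi_params)
        assert np.allclose(occ, [1, 0, 0, 0, 0])

    def test_mu_one_is_binomial(self, gi_params):
        """Without cooperativity the four sites are independent and the
        occupancy is Binomial(4, p) with per-site odds k56·g/k65."""
        g = 12.5
        p_indep = gi_params.replace(mu=1.0)
        odds = p_indep.k56 * g / p_indep.k65
        p = odds / (1.0 + odds)
        expected = np.array([comb(4, n) * p**n * (1 - p) ** (4 - n) for n in range(5)])
        occ = girk_occupancy_closed_form(g, p_indep)
        assert np.allclose(occ, expected, rtol=1e-12)

    @pytest.mark.parametrize("gbg", [0.5, 3.0, 12.5, 27.0, 49.0])
    def test_matches_binding_only_ode(self, gi_params, gbg):
        """Integrating just the GIRK ladder at clamped free Gβγ converges to
        the closed-form occupancy (independent ODE oracle)."""
        p = gi_params

        def ladder(t, g):
            dg = np.zeros(5)
            for n in range(1, 5):
                fwd = (5 - n) * p.k56 * gbg * g[n - 1]
                bwd = n * p.mu ** (n - 1) * p.k65 * g[n]
                dg[n - 1] -= fwd - bwd
                dg[n] += fwd - bwd
            return dg

        sol = solve_ivp(ladder, (0, 50.0), [1, 0, 0, 0, 0], method="BDF",
                        rtol=1e-10, atol=1e-12)
        assert sol.success
        occ = girk_occupancy_closed_form(gbg, p)
        assert np.allclose(sol.y[:, -1], occ, atol=1e-6)

    def test_non_depleting_mode_reaches_same_occupancy(self, gi_params, geometry):
        """Package route: non-depleting simulation with only GIRK + free Gβγ
        holds Gβγ clamped and lands on the closed form."""
        gbg = 12.5
        y0 = state_vector(Gbg=gbg, girk0=geometry.girk_density)
        prot = StimulusProtocol.constant(0.0, 50.0)
        tc = simulate(gi_params, geometry, prot, 50.0, initial=y0,
                      deplete_gbg=False)
        occ = tc.states[-1, 6:11] / geometry.girk_density
        assert tc["Gbg"][-1] == pytest.approx(gbg, rel=1e-9)
        assert np.allclose(occ, girk_occupancy_closed_form(gbg, gi_params), atol=1e-6)


class TestBasalEquilibrium:
    def test_quadratic_closed_form(self, gi_params, geometry):
        """With negligible GIRK, basal free Gβγ solves
        x² + K·x − K·G_total = 0 with K = k54/k45 (2D units)."""
        geo = geometry.replace(girk_density=1e-12)
        K = gi_params.k54 / gi_params.k45
        g_tot = geo.trimer_density
        root = (-K + math.sqrt(K * K + 4 * K * g_tot)) / 2.0
        y = basal_equilibrium(gi_params, geo)
        assert y[SPECIES.index("Gbg")] == pytest.approx(root, rel=1e-8)

    def test_irreversible_limit(self, gi_params, geometry):
        y = basal_equilibrium(gi_params.replace(k54=0.0), geometry)
        assert y[SPECIES.index("Gbg")] == 0.0
        assert y[SPECIES.index("T")] == geometry.trimer_density

    def test_is_fixed_point(self, gi_params, geometry):
        y = basal_equilibrium(gi_params, geometry)
        assert np.abs(derivatives(y, gi_params, 0.0)).max() < 1e-8

    def test_flat_trajectory_without_stimulus(self, gi_params, geometry):
        prot = StimulusProtocol.constant(0.0, 10.0)
        tc = simulate(gi_params, geometry, prot, 10.0, initial="basal")
        rel_span = np.ptp(tc.states, axis=0) / (tc.states.max(axis=0) + 1e-12)
        assert rel_span.max() < 1e-6


class TestSimulate:
    def test_activation_reaches_steady_state_within_seconds(self, gi_params, geometry):
        """A k12 step drives GIRK·βγ₄ to ≥ 95% of its steady value inside 10 s."""
        prot = StimulusProtocol.step(gi_params.k12, 10.0)
        tc = simulate(gi_params, geometry, prot, 10.0)
        ss = steady_state(gi_params, geometry, gi_params.k12)
        girk4_ss = ss[SPECIES.index("girk4")]
        assert tc["girk4"][-1] >= 0.95 * girk4_ss
        assert tc["girk4"][0] < 0.05 * girk4_ss

    def test_conservation_drift(self, gi_params, geometry):
        prot = StimulusProtocol.step(gi_params.k12, 10.0)
        tc = simulate(gi_params, geometry, prot, 10.0)
        assert tc.conservation_drift() < 1e-6

    def test_non_negative_trajectory(self, gi_params, geometry):
        prot = StimulusProtocol.step(gi_params.k12, 10.0)
        tc = simulate(gi_params, geometry, prot, 10.0)
        assert np.all(tc.states >= 0.0)

    def test_grid_independence(self, gi_params, geometry):
        """Doubling the output grid must not change shared state values
        beyond solver tolerance."""
        prot = StimulusProtocol.step(gi_params.k12, 10.0)
        coarse = np.linspace(0, 10, 101)
        fine = np.linspace(0, 10, 201)
        tc1 = simulate(gi_params, geometry, prot, 10.0, output_grid=coarse)
        tc2 = simulate(gi_params, geometry, prot, 10.0, output_grid=fine)
        shared = tc2.states[::2]
        scale = np.abs(tc1.states).max()
        assert np.abs(tc1.states - shared).max() < 1e-5 * scale

    def test_wash_off_protocol_returns_toward_basal(self, gi_params, geometry):
        """Agonist on for 10 s then off: girk4 decays after wash-off."""
        prot = StimulusProtocol(((0.0, 10.0, gi_params.k12), (10.0, 40.0, 0.0)))
        tc = simulate(gi_params, geometry, prot, 40.0, initial="basal")
        i_on = np.searchsorted(tc.t, 10.0)
        assert tc["girk4"][-1] < 0.5 * tc["girk4"][i_on]

    def test_protocol_must_cover_window(self, gi_params, geometry):
        prot = StimulusProtocol.step(gi_params.k12, 5.0)
        with pytest.raises(kin.InvalidProtocolError):
            simulate(gi_params, geometry, prot, 10.0)

    def test_protocol_validation(self):
        with pytest.raises(kin.InvalidProtocolError):
            StimulusProtocol(((1.0, 2.0, 0.1),))  # does not start at 0
        with pytest.raises(kin.InvalidProtocolError):
            StimulusProtocol(((0.0, 2.0, 0.1), (3.0, 4.0, 0.1)))  # gap
        with pytest.raises(kin.InvalidProtocolError):
            StimulusProtocol(((0.0, 2.0, -0.1),))


class TestSteadyState:
    def test_matches_basal_at_zero_k12(self, gi_params, geometry):
        y = steady_state(gi_params, geometry, 0.0)
        y_basal = basal_equilibrium(gi_params, geometry)
        assert np.allclose(y, y_basal, rtol=1e-6, atol=1e-9)

    def test_girk4_increases_with_k12(self, gi_params, geometry):
        i4 = SPECIES.index("girk4")
        lo = steady_state(gi_params, geometry, gi_params.k12 / 10.0)[i4]
        hi = steady_state(gi_params, geometry, gi_params.k12)[i4]
        assert hi > lo

    def test_per_receptor_generation_bounded_by_k23(self, gi_params, geometry):
        """At steady state the per-receptor Gβγ generation rate
        k23·RT/receptor_density cannot exceed k23 itself (~1 s⁻¹)."""
        y = steady_state(gi_params, geometry, gi_params.k12)
        rate = gi_params.k23 * y[SPECIES.index("RT")] / geometry.receptor_density
        assert 0.0 < rate <= gi_params.k23

    def test_girk4_increases_with_trimer_density(self, gi_params, geometry):
        i4 = SPECIES.index("girk4")
        lo = steady_state(gi_params, geometry.replace(trimer_density=50.0), gi_params.k12)[i4]
        hi = steady_state(gi_params, geometry.replace(trimer_density=100.0), gi_params.k12)[i4]
        assert hi > lo


class TestSweep:
    def test_single_zero_point_is_basal(self, gi_params, geometry):
        tab = sweep_k12(gi_params, geometry, [0.0])
        basal_girk4 = basal_equilibrium(gi_params, geometry)[SPECIES.index("girk4")]
        assert tab["girk4"].iloc[0] == pytest.approx(basal_girk4, abs=1e-8)

    def test_monotone_over_log_grid(self, gi_params, geometry):
        grid = np.geomspace(gi_params.k12 * 1e-3, gi_params.k12 * 10.0, 12)
        tab = sweep_k12(gi_params, geometry, grid)
        girk4 = tab["girk4"].to_numpy()
        assert np.all(np.diff(girk4) >= -1e-10 * girk4.max())

    def test_steep_region_near_default(self, gi_params, geometry):
        tab = sweep_k12(gi_params, geometry, [gi_params.k12 / 10.0, gi_params.k12])
        ratio = tab["girk4"].iloc[1] / tab["girk4"].iloc[0]
        assert ratio > 5.0

    def test_unsorted_grid_rejected(self, gi_params, geometry):
        with pytest.raises(kin.InvalidProtocolError):
            sweep_k12(gi_params, geometry, [0.2, 0.1])
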