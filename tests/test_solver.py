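"""1-D explicit scheme: stencil, clearance, stability, oracles, ledger."""

import numpy as np
import pytest
from scipy.special import erfc

from vancoelute.errors import StabilityError, ValidationError
from vancoelute.solver import (
    ClearanceSpec,
    Grid1D,
    LayerSpec,
    decay_increment,
    dirichlet,
    flux_in,
    mass_balance,
    no_flux,
    simulate_1d,
    sink,
    step_1d,
)

NO_CLEAR = ClearanceSpec(None)


def uniform_grid(L=1.0, D=1.0, dx=0.5, area=1.0):
    return Grid1D([LayerSpec("m", L, D)], dx=dx, cross_section_area=area)


class TestDecayIncrement:
    def test_printed_increment_form(self):
        # Δt·(ln½/t½)·C·0.5^(Δt/t½) at C=100, Δt=0.01, t½=4
        assert decay_increment(100.0, 0.01, ClearanceSpec(4.0)) == pytest.approx(
            -0.17299, abs=2e-5
        )

    def test_zero_concentration_clears_nothing(self):
        assert decay_increment(0.0, 0.5, ClearanceSpec(4.0)) == 0.0

    def test_disabled_clearance_returns_zero(self):
        assert decay_increment(123.0, 0.5, NO_CLEAR) == 0.0

    def test_small_step_limit_matches_exact_halving(self):
        # accumulate increments over one half-life with dt→0
        C = 100.0
        dt = 1e-3
        spec = ClearanceSpec(4.0)
        for _ in range(4000):
            C += decay_increment(C, dt, spec)
        assert C == pytest.approx(50.0, rel=5e-3)


class TestStep1D:
    def test_uniform_field_is_steady(self):
        g = uniform_grid(L=2.0, dx=0.5)
        C = np.full(4, 7.0)
        new, _ = step_1d(C, 0.0, g, no_flux(), no_flux(), NO_CLEAR, 0.01)
        np.testing.assert_allclose(new, C)

    def test_single_cell_flux_gain(self):
        # one cell, J = 1 µg·mm⁻²·h⁻¹: concentration gains 1000·(Δt/Δx)·J µg/mL
        g = Grid1D([LayerSpec("m", 1.0, 1e-6)], dx=1.0, cross_section_area=1.0)
        C = np.zeros(1)
        new, deltas = step_1d(C, 0.0, g, flux_in(lambda t: 1.0), no_flux(), NO_CLEAR, 0.01)
        assert new[0] == pytest.approx(1000.0 * 0.01 / 1.0 * 1.0)
        assert deltas["influx"] == pytest.approx(0.01)  # A·J·dt µg

    def test_two_cell_diffusive_exchange(self):
        # C=(100,0), D·Δt/Δx² = 0.1 → (90, 10)
        g = uniform_grid(L=2.0, D=1.0, dx=1.0)
        new, _ = step_1d(np.array([100.0, 0.0]), 0.0, g, no_flux(), no_flux(), NO_CLEAR, 0.1)
        np.testing.assert_allclose(new, [90.0, 10.0])

    def test_violating_cfl_raises(self):
        g = uniform_grid()
        with pytest.raises(StabilityError, match="stability bound"):
            step_1d(np.zeros(g.n_cells), 0.0, g, no_flux(), no_flux(), NO_CLEAR,
                    3 * g.max_stable_dt())

    def test_state_size_mismatch(self):
        g = uniform_grid()
        with pytest.raises(ValidationError):
            step_1d(np.zeros(99), 0.0, g, no_flux(), no_flux(), NO_CLEAR, 1e-3)


class TestSimulate1D:
    def test_zero_everything_stays_zero(self):
        g = uniform_grid(L=2.0, dx=0.25)
        res = simulate_1d(g, no_flux(), no_flux(), NO_CLEAR, t_end=1.0)
        assert np.all(res.states == 0.0)
        assert res.ledger.closure_error() == 0.0

    def test_constant_boundary_matches_erfc_profile(self):
        """Dirichlet C0 on a long domain reproduces C/C0 = erfc(x/2√(Dt))."""
        g = Grid1D([LayerSpec("m", 10.0, 1.0)], dx=0.05)
        res = simulate_1d(g, dirichlet(1.0), no_flux(), NO_CLEAR, t_end=1.0)
        exact = erfc(g.cell_centers / (2 * np.sqrt(res.times[-1])))
        mask = exact > 0.05
        rel = np.abs(res.final_state[mask] - exact[mask]) / exact[mask]
        assert rel.max() < 0.01

    def test_pure_decay_matches_half_life_law(self):
        """Uniform field, no flux: six half-lives → (1/2)^6 of the start."""
        g = Grid1D([LayerSpec("m", 1.0, 1e-3)], dx=0.5)
        res = simulate_1d(g, no_flux(), no_flux(), ClearanceSpec(4.0),
                          t_end=24.0, dt=0.004, init=100.0)
        ratio = res.final_state[0] / 100.0
        assert ratio == pytest.approx(0.5**6, rel=5e-3)
        assert res.ledger.closure_error() < 1e-12

    def test_exact_clearance_mode_is_exact(self):
        g = Grid1D([LayerSpec("m", 1.0, 1e-3)], dx=0.5)
        res = simulate_1d(g, no_flux(), no_flux(), ClearanceSpec(4.0, mode="exact"),
                          t_end=24.0, dt=0.04, init=100.0)
        assert res.final_state[0] / 100.0 == pytest.approx(0.5**6, rel=1e-12)

    def test_flux_in_conserves_mass(self):
        g = uniform_grid(L=2.0, dx=0.25, area=3.0)
        res = simulate_1d(g, flux_in(lambda t: 0.5), no_flux(), NO_CLEAR, t_end=2.0)
        bal = mass_balance(res)
        assert bal["influx_ug"] == pytest.approx(3.0 * 0.5 * 2.0, rel=1e-9)
        assert bal["closure_error"] < 1e-12

    def test_clearance_ledger_closes(self):
        g = uniform_grid(L=2.0, dx=0.25)
        res = simulate_1d(g, flux_in(lambda t: 0.5), no_flux(), ClearanceSpec(2.0),
                          t_end=4.0)
        led = res.ledger
        assert led.cleared == pytest.approx(led.influx - led.stored, rel=1e-9)
        assert led.closure_error() < 1e-12

    def test_impulse_survives_many_steps_near_bound(self):
        """dt at 0.99× the Δx²/(6D) bound: 10⁴ steps, no negatives, no NaNs."""
        g = Grid1D([LayerSpec("m", 10.0, 1.0)], dx=0.5)
        dt = 0.99 * g.max_stable_dt()
        init = np.zeros(g.n_cells)
        init[10] = 1000.0
        res = simulate_1d(g, no_flux(), no_flux(), NO_CLEAR, t_end=dt * 10_000, dt=dt,
                          init=init, record_every=dt * 1000)
        assert np.all(np.isfinite(res.states))
        assert res.states.min() >= 0.0

    def test_overstepping_bound_raises_quickly(self):
        g = Grid1D([LayerSpec("m", 10.0, 1.0)], dx=0.5)
        init = np.zeros(g.n_cells)
        init[10] = 1000.0
        with pytest.raises(StabilityError):
            simulate_1d(g, no_flux(), no_flux(), NO_CLEAR, t_end=1.0,
                        dt=3 * g.max_stable_dt(), init=init)

    def test_negative_initial_rejected(self):
        g = uniform_grid()
        with pytest.raises(ValidationError):
            simulate_1d(g, no_flux(), no_flux(), NO_CLEAR, t_end=1.0,
                        init=np.array([-1.0, 0.0]))


class TestLayeredGrids:
    def test_non_integer_layer_rejected(self):
        with pytest.raises(ValidationError, match="integer number of cells"):
            Grid1D([LayerSpec("a", 1.05, 1.0)], dx=0.5)

    def test_interface_flux_continuity_at_steady_state(self):
        """Two contrasting layers at steady flux: interface flux = influx."""
        g = Grid1D([LayerSpec("a", 1.0, 1.0), LayerSpec("b", 1.0, 0.2)], dx=0.25)
        res = simulate_1d(g, flux_in(lambda t: 1.0), sink(), NO_CLEAR, t_end=300.0)
        C = res.final_state
        i = 3  # last cell of layer a
        flux = g.face_D[i] * (C[i] - C[i + 1]) / g.dx / 1000.0  # µg·mm⁻²·h⁻¹
        assert flux == pytest.approx(1.0, rel=1e-6)

    def test_harmonic_mean_face_diffusivity(self):
        g = Grid1D([LayerSpec("a", 0.5, 1.0), LayerSpec("b", 0.5, 0.25)], dx=0.5)
        assert g.face_D[0] == pytest.approx(2 * 1.0 * 0.25 / 1.25)

    def test_grid_convergence_on_fixed_scenario(self):
        """Halving dx changes the 24-h average by a shrinking amount."""
        from vancoelute.postprocess import average_concentration

        vals = []
        for dx in (0.5, 0.25, 0.125):
            g = Grid1D([LayerSpec("m", 3.0, 0.7488)], dx=dx)
            res = simulate_1d(g, flux_in(lambda t: 0.01), sink(), ClearanceSpec(4.0),
                              t_end=24.0)
            vals.append(average_concentration(res)[-1])
        diffs = np.abs(np.diff(vals))
        assert diffs[1] < diffs[0]
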