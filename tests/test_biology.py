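"""Phenotype switching, sources, oxygen metabolism and cell transport."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomech import (CellFields, SimulationParams, cell_transport_step,
                      oxygen_step, phenotype_sources, switch_factors)
from gliomech.biology import CFLError


class TestSwitchFactors:
    def test_half_at_thresholds(self, params):
        h_pm, h_mp, _ = switch_factors(params.xi_h, params)
        assert h_pm == pytest.approx(0.5) and h_mp == pytest.approx(0.5)
        _, _, h_nec = switch_factors(params.xi_n, params)
        assert h_nec == pytest.approx(0.5)

    def test_saturation_far_above_threshold(self, params):
        h_pm, h_mp, _ = switch_factors(params.xi_h + 10 * params.lambda_switch, params)
        assert h_pm < 1e-8 and h_mp > 1 - 1e-8

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.floats(0.0, 50.0))
    def test_partition_of_unity_and_range(self, n):
        p = SimulationParams()
        h_pm, h_mp, h_nec = switch_factors(n, p)
        assert h_pm + h_mp == pytest.approx(1.0, abs=1e-15)
        for h in (h_pm, h_mp, h_nec):
            assert 0.0 <= h <= 1.0  # saturates to exactly 0/1 in floats far out


class TestPhenotypeSources:
    def test_empty_state_is_silent(self, params):
        S = phenotype_sources(0.0, 0.0, 0.0, 2.0, params)
        assert all(s == 0.0 for s in S)

    def test_at_carrying_capacity_transitions_only(self, params):
        C_q = params.C_q
        S_p, S_m, S_n = phenotype_sources(C_q / 2, C_q / 4, C_q / 4, 2.0, params)
        assert S_p + S_m + S_n == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(cp=st.floats(0, 8e5), cm=st.floats(0, 8e5), cn=st.floats(0, 8e5),
           n=st.floats(0.0, 4.0))
    def test_transitions_conserve_cells(self, cp, cm, cn, n):
        """S_p + S_m + S_n must equal the pure proliferation terms."""
        p = SimulationParams()
        S_p, S_m, S_n = phenotype_sources(cp, cm, cn, n, p)
        ctot = cp + cm + cn
        logistic = max(0.0, 1.0 - ctot / p.C_q)
        expected = (cp / p.tau_p + p.h_m_flag * cm / p.tau_m) * logistic * n / p.n_max
        assert S_p + S_m + S_n == pytest.approx(expected, rel=1e-9, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(cm=st.floats(0, 8e5), n=st.floats(0.0, 4.0))
    def test_necrosis_never_reverses(self, cm, n):
        p = SimulationParams()
        *_, S_n = phenotype_sources(1e4, cm, 1e4, n, p)
        assert S_n >= 0.0

    def test_proliferation_off_when_total_mass_fixed(self, params, grid):
        """With infinite doubling times the sources only shuffle phenotypes."""
        p = params.replace(tau_p=1e18, tau_m=1e18)
        S_p, S_m, S_n = phenotype_sources(1e5, 5e4, 1e4, 0.9, p)
        assert S_p + S_m + S_n == pytest.approx(0.0, abs=1e-6)


class TestOxygenStep:
    def test_uniform_no_cells_unchanged(self, params, grid):
        n = np.full(grid.n_nodes, params.n0)
        zero = np.zeros(grid.n_nodes)
        out = oxygen_step(n, zero, zero, 1e-3, params, grid)
        assert np.allclose(out, n, atol=1e-12)

    def test_pure_uptake_linear_decay(self, params, grid):
        """With diffusion off, n(t) = n0 - (alpha_p C_p) t; the depletion
        rate at the seeding density is 966 mg/(L day)."""
        p = params.replace(D_ox=0.0)
        C_p = np.full(grid.n_nodes, 7.0e4)
        zero = np.zeros(grid.n_nodes)
        rate = p.alpha_p * 7.0e4
        assert rate == pytest.approx(966.0, rel=1e-9)
        n = np.full(grid.n_nodes, p.n0)
        dt = 1e-4
        for _ in range(10):
            n = oxygen_step(n, C_p, zero, dt, p, grid)
        assert np.allclose(n, p.n0 - rate * 10 * dt, rtol=1e-9)

    def test_uptake_clamped_at_zero(self, params, grid):
        p = params.replace(D_ox=0.0)
        C_p = np.full(grid.n_nodes, 7.0e4)
        zero = np.zeros(grid.n_nodes)
        n = np.full(grid.n_nodes, 1e-4)
        out = oxygen_step(n, C_p, zero, 1e-2, p, grid)
        assert np.all(out >= 0.0)

    def test_psbc_pins_boundary(self, params, grid):
        p = params.replace(oxygen_bc="PSBC")
        n = np.full(grid.n_nodes, 2.0)
        C_p = np.full(grid.n_nodes, 1e4)
        zero = np.zeros(grid.n_nodes)
        out = oxygen_step(n, C_p, zero, 1e-3, p, grid)
        assert out[-1] == pytest.approx(p.n0)


class TestCellTransport:
    def test_frozen_configuration_is_fixed_point(self, params, grid):
        """No drift, no diffusion, negligible sources: fields unchanged."""
        p = params.replace(switch_mode="stiff", D_m=0.0, M0=0.0, sigma_att=0.0,
                           tau_p=1e18, tau_m=1e18, tau_pm=1e18, tau_mp=1e18,
                           tau_n=1e18)
        f = CellFields(np.where(grid.r < 0.3, 1e5, 0.0),
                       np.full(grid.n_nodes, 1e3), np.zeros(grid.n_nodes))
        n = np.full(grid.n_nodes, p.n0)
        out = cell_transport_step(f, np.zeros(grid.n_nodes), 1e-3, n, p, grid)
        assert np.allclose(out.C_p, f.C_p, rtol=1e-12, atol=1e-9)
        assert np.allclose(out.C_m, f.C_m, rtol=1e-12, atol=1e-9)

    def test_transport_conserves_total_mass_without_sources(self, params, grid, rng):
        p = params.replace(tau_p=1e18, tau_m=1e18, tau_pm=1e18, tau_mp=1e18,
                           tau_n=1e18)
        f = CellFields(rng.random(grid.n_nodes) * 1e5,
                       rng.random(grid.n_nodes) * 1e4,
                       rng.random(grid.n_nodes) * 1e3)
        v = 0.5 * np.sin(5 * grid.r)
        v[0] = 0.0
        n = np.full(grid.n_nodes, p.n0)
        m0 = grid.integrate(f.C_tot)
        out = f
        for _ in range(50):
            out = cell_transport_step(out, v, 2e-4, n, p, grid)
        assert grid.integrate(out.C_tot) == pytest.approx(m0, rel=1e-8)

    def test_exponential_growth_oracle(self, params, grid):
        """Uniform proliferative population well below capacity and at full
        oxygen grows as exp(t/tau_p) to within 1% over one day."""
        p = params.replace(switch_mode="stiff", n0=11.0, xi_h=1.0, xi_n=0.8)
        C0 = 10.0
        f = CellFields(np.full(grid.n_nodes, C0), np.zeros(grid.n_nodes),
                       np.zeros(grid.n_nodes))
        n = np.full(grid.n_nodes, p.n0)   # n/n_max = 1, h_pm ~ 1e-9
        v = np.zeros(grid.n_nodes)
        dt, steps = 1e-3, 1000
        out = f
        for _ in range(steps):
            out = cell_transport_step(out, v, dt, n, p, grid)
        expected = C0 * np.exp(1.0 / p.tau_p)
        assert np.allclose(out.C_p, expected, rtol=1e-2)

    def test_subcycling_handles_fast_flow(self, params, grid):
        f = CellFields(np.where(grid.r < 0.3, 1e5, 0.0), np.zeros(grid.n_nodes),
                       np.zeros(grid.n_nodes))
        v = np.full(grid.n_nodes, 30.0)  # CFL ~ 1.2 at dt=2e-4 -> sub-cycled
        v[0] = 0.0
        n = np.full(grid.n_nodes, params.n0)
        m0 = grid.integrate(f.C_tot)
        p = params.replace(tau_p=1e18, tau_pm=1e18, tau_mp=1e18, tau_n=1e18,
                           tau_m=1e18)
        out = cell_transport_step(f, v, 2e-4, n, p, grid)
        assert grid.integrate(out.C_tot) == pytest.approx(m0, rel=1e-8)

    def test_absurd_flow_raises(self, params, grid):
        f = CellFields(np.ones(grid.n_nodes), np.zeros(grid.n_nodes),
                       np.zeros(grid.n_nodes))
        v = np.full(grid.n_nodes, 1e6)
        n = np.full(grid.n_nodes, params.n0)
        with pytest.raises(CFLError):
            cell_transport_step(f, v, 2e-4, n, params, grid)

    def test_fields_stay_non_negative(self, params, grid, rng):
        f = CellFields(rng.random(grid.n_nodes) * 1e5, rng.random(grid.n_nodes) * 1e4,
                       np.zeros(grid.n_nodes))
        v = 1.0 * np.sin(8 * grid.r)
        v[0] = 0.0
        n = np.full(grid.n_nodes, 0.5)  # hypoxic everywhere: heavy switching
        out = f
        for _ in range(20):
            out = cell_transport_step(out, v, 2e-4, n, params, grid)
        out.validate()  # raises on negativity or non-finite values
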