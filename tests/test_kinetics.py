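"""Rate laws, diffusion, membrane-potential dynamics and the steady-state
solver, checked against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.optimize import fsolve

from aomsr.kinetics import (
    Simulator,
    SystemState,
    diffusion_flux,
    integrate_to_steady_state,
    membrane_potential_rate,
    reaction_rate,
)
from aomsr.model_core import Enzyme, Reaction
from aomsr.thermo import ThermoContext

from conftest import make_chain_model

CTX = ThermoContext()


class TestReactionRate:
    def _setup(self, dg0=0.0, chi=1.0):
        rxn = Reaction("R", {"A": -1, "B": 1}, delta_g0_prime=dg0, chi_e=chi)
        enz = Enzyme("R", phi=0.01, phi_max=0.1, kcat_fwd=10.0,
                     km_map={"A": 1e-6}, molar_mass=4.752e5)
        return rxn, enz

    def test_zero_at_equilibrium(self):
        rxn, enz = self._setup()
        st = SystemState({"A": 1e-3, "B": 1e-3})
        assert reaction_rate(enz, rxn, st, 0.0, CTX) == 0.0

    def test_zero_at_zero_abundance(self):
        rxn, enz = self._setup(dg0=-10.0)
        enz = Enzyme("R", phi=0.0, phi_max=0.1, kcat_fwd=10.0,
                     km_map={"A": 1e-6}, molar_mass=4.752e5)
        st = SystemState({"A": 1e-3, "B": 1e-3})
        assert reaction_rate(enz, rxn, st, 0.0, CTX) == 0.0

    def test_thermodynamic_throttle_value(self):
        # dG = -17.2 kJ/mol, chi 1: factor = 1 - exp(-17.2/RT) = 1 - e^-6.94
        rxn, enz = self._setup(dg0=-17.2)
        st = SystemState({"A": 1.0, "B": 1.0})  # Q = 1, saturated
        v = reaction_rate(enz, rxn, st, 0.0, CTX)
        expected = enz.vmax() * (1.0 / (1.0 + 1e-6)) * (1 - math.exp(-17.2 / CTX.rt))
        assert v == pytest.approx(expected, rel=1e-9)
        assert v / enz.vmax() == pytest.approx(0.999, abs=2e-3)

    def test_sign_follows_free_energy(self):
        rxn, enz = self._setup(dg0=0.0)
        fwd = reaction_rate(enz, rxn, SystemState({"A": 1e-2, "B": 1e-4}),
                            0.0, CTX)
        rev = reaction_rate(enz, rxn, SystemState({"A": 1e-4, "B": 1e-2}),
                            0.0, CTX)
        assert fwd > 0 > rev


class TestDiffusion:
    def test_zero_gradient_zero_flux(self):
        rxn = Reaction("D", {"A@e": -1, "A@RM": 1}, kind="diffusion",
                       rate_constant=100.0)
        st = SystemState({"A@e": 5e-3, "A@RM": 5e-3})
        assert diffusion_flux(rxn, st) == 0.0

    def test_linearity_and_antisymmetry(self):
        rxn = Reaction("D", {"A@e": -1, "A@RM": 1}, kind="diffusion",
                       rate_constant=100.0)
        f1 = diffusion_flux(rxn, SystemState({"A@e": 2e-3, "A@RM": 1e-3}))
        f2 = diffusion_flux(rxn, SystemState({"A@e": 3e-3, "A@RM": 1e-3}))
        f3 = diffusion_flux(rxn, SystemState({"A@e": 1e-3, "A@RM": 2e-3}))
        assert f2 == pytest.approx(2 * f1)
        assert f3 == pytest.approx(-f1)

    def test_uptake_capacity_ratio_is_unity(self, fixture_model):
        assert fixture_model.geometry.uptake_flux_ratio() == 1.0


class TestMembranePotentialRate:
    def test_no_translocation_no_charging(self):
        rxns = [Reaction("R", {"A": -1, "B": 1}, nu_plus=0.0)]
        assert membrane_potential_rate({"R": 5.0}, rxns, 0.03) == 0.0

    def test_unit_conversion(self):
        # nu+ = 2, v = 1 mmol/g/d, C_m = 96.485 C/V/g -> 2 V per day
        rxns = [Reaction("R", {"A": -1, "B": 1}, nu_plus=2.0)]
        out = membrane_potential_rate({"R": 1.0}, rxns, 96.485)
        assert out == pytest.approx(2.0, rel=1e-6)

    def test_rejects_nonpositive_capacitance(self):
        with pytest.raises(ValueError):
            membrane_potential_rate({}, [], 0.0)


class TestSteadyState:
    def test_closed_chain_reaches_equilibrium(self):
        """A<->B<->C with known K: pools end at the analytic equilibrium."""
        model = make_chain_model(dg1=-3.0, dg2=-1.0, closed=True)
        res = integrate_to_steady_state(model)
        assert res.converged
        k1 = math.exp(3.0 / CTX.rt)
        k2 = math.exp(1.0 / CTX.rt)
        total = 3.0e-3
        a = total / (1 + k1 + k1 * k2)
        c = res.state.concentrations
        assert c["A@RM"] == pytest.approx(a, rel=1e-6)
        assert c["B@RM"] == pytest.approx(a * k1, rel=1e-6)
        assert c["C@RM"] == pytest.approx(a * k1 * k2, rel=1e-6)

    def test_closed_chain_conserves_mass(self):
        model = make_chain_model(closed=True)
        res = integrate_to_steady_state(model)
        total = sum(res.state.concentrations[s]
                    for s in ("A@RM", "B@RM", "C@RM"))
        assert total == pytest.approx(3.0e-3, rel=1e-6)

    def test_open_chain_matches_bruteforce_root(self):
        """Steady state equals an independently coded root-find of the
        rate equations to 1e-8 relative."""
        model = make_chain_model(dg1=-3.0, dg2=-1.0, closed=False,
                                 exchange_k=1.0, v1=40.0, v2=60.0)
        res = integrate_to_steady_state(model)
        assert res.converged

        rt = CTX.rt
        k_ex, a_out, c_out = 1.0, 2.0e-3, 1.0e-4
        k1, k2 = math.exp(3.0 / rt), math.exp(1.0 / rt)
        km = 1e-6

        def rates(x):
            a, b, c = x
            v_in = k_ex * (a_out - a)
            v1 = 40.0 * (a / (a + km)) * (1 - (b / a) / k1)
            v2 = 60.0 * (b / (b + km)) * (1 - (c / b) / k2)
            v_out = k_ex * (c - c_out)
            return [v_in - v1, v1 - v2, v2 - v_out]

        x0 = np.array([1e-3, 1e-3, 1e-3])
        sol = fsolve(rates, x0, xtol=1e-13)
        got = np.array([res.state.concentrations[s]
                        for s in ("A@RM", "B@RM", "C@RM")])
        assert np.allclose(got, sol, rtol=1e-8)
        # the chain carries positive flux
        assert res.fluxes[("TOY", "R1")] > 0

    def test_no_flux_against_free_energy(self, fixture_steady):
        for key, v in fixture_steady.fluxes.items():
            dg = fixture_steady.delta_g[key]
            assert v * dg <= 1e-9, (key, v, dg)

    def test_charge_balance_at_steady_state(self, fixture_model,
                                            fixture_steady):
        for cname, cell in fixture_model.cells.items():
            net = sum(r.nu_plus * fixture_steady.fluxes[(cname, r.id)]
                      for r in cell.reactions)
            assert abs(net) < 1e-6

    def test_flux_balance_per_metabolite(self, fixture_model,
                                         fixture_steady):
        net = {}
        for (cname, rid), v in fixture_steady.fluxes.items():
            for sid, nu in fixture_model.cells[cname].reaction(rid). \
                    equation.items():
                net[sid] = net.get(sid, 0.0) + nu * v
        for sid, imbalance in net.items():
            if fixture_model.metabolites[sid].clamped or sid == "H2O":
                continue
            assert abs(imbalance) < 1e-6, sid

    def test_nonconvergence_is_reported_not_silent(self):
        model = make_chain_model(closed=False)
        sim = Simulator(model)
        res = sim.solve_steady_state(horizon=1e-9, tol=1e-12, polish=False)
        assert res.converged is False
        assert res.residual > 0


class TestKnockouts:
    """Removing either membrane-potential-driven activation step flips the
    methane-activating enzyme into net methane production fed by ATP
    hydrolysis."""

    @pytest.mark.parametrize("ko", ["HDR", "MTR"])
    def test_translocation_knockout_reverses_methane_flux(self, ko):
        from aomsr import build_aomsr_model

        model = build_aomsr_model()
        model.cells["ANME"].reaction(ko).nu_plus = 0.0
        res = integrate_to_steady_state(model)
        assert res.converged
        assert res.flux("ANME", "MCR") < 0
        assert res.atp_flux("ANME") < 0  # ATP hydrolysed, not made


class TestTimeCourse:
    def test_reports_requested_times(self):
        model = make_chain_model(closed=True)
        sim = Simulator(model)
        states = sim.time_course([0.0, 1.0, 5.0])
        assert [s.time for s in states] == [0.0, 1.0, 5.0]
        assert states[0].concentrations["A@RM"] == pytest.approx(1e-3)
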