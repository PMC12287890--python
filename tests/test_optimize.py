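"""Proteome/ion-translocation optimization and the energy-partition scan."""

import numpy as np
import pytest

from aomsr.kinetics import Simulator
from aomsr.model_core import CellModel, ConsortiumModel, Enzyme, Metabolite, \
    Reaction
from aomsr.optimize import (
    couple_consortium,
    crossing_point,
    maximize_atp_flux,
    pareto_energy_partition,
    set_diet_potential,
)

from conftest import _species, make_symmetric_consortium


def _linear_cell(phi1=0.005, phi2=0.005, cap=0.02, v2_scale=1.0):
    """S ->(R1) M ->(ATPase) P with clamped ends; the second step is the
    scored 'ATP' step, so pathway flux is the optimisation currency."""
    mets = {
        "S@e": _species("S@e", 1e-3, clamped=True, compartment="environment"),
        "M@RM": _species("M@RM", 1e-3),
        "P@e": _species("P@e", 1e-3, clamped=True, compartment="environment"),
    }
    reactions = [
        Reaction("R1", {"S@e": -1, "M@RM": 1}, kind="cytoplasmic",
                 delta_g0_prime=-8.0),
        Reaction("ATPase", {"M@RM": -1, "P@e": 1}, kind="cytoplasmic",
                 delta_g0_prime=-8.0),
    ]
    enzymes = {
        "R1": Enzyme("R1", phi=phi1, phi_max=0.1, kcat_fwd=100.0,
                     km_map={"S@e": 1e-6}, molar_mass=4.752e5),
        "ATPase": Enzyme("ATPase", phi=phi2, phi_max=0.1,
                         kcat_fwd=100.0 * v2_scale,
                         km_map={"M@RM": 1e-6}, molar_mass=4.752e5),
    }
    cell = CellModel(name="TOY", reactions=reactions, enzymes=enzymes,
                     membrane_potential=0.0, substrate_id="S@e",
                     atpase_id="ATPase", cytoplasm_pool_cap=cap,
                     pathway_chi={"R1": 1, "ATPase": 1})
    return ConsortiumModel(metabolites=mets, cells={"TOY": cell})


class TestMaximizeAtpFlux:
    def test_single_step_boundary_optimum(self):
        """Flux proportional to abundance: the optimum is the bound."""
        model = _linear_cell(phi1=0.05, phi2=0.01, cap=1.0)
        # make the first step non-limiting and optimise only the second
        res = maximize_atp_flux(model, "TOY", optimize_phi=["ATPase"],
                                seed=3, maxiter=200, restarts=1)
        assert res.control.phi["ATPase"] == pytest.approx(0.1, abs=1e-6)

    def test_two_step_split_matches_grid_oracle(self):
        """Optimal split of a shared proteome pool vs. brute-force grid."""
        model = _linear_cell(cap=0.02, v2_scale=0.5)

        def flux_at(phi1):
            trial = model.copy()
            from dataclasses import replace
            c = trial.cells["TOY"]
            c.enzymes["R1"] = replace(c.enzymes["R1"], phi=phi1)
            c.enzymes["ATPase"] = replace(c.enzymes["ATPase"],
                                          phi=0.02 - phi1)
            sim = Simulator(trial, active_cells=["TOY"])
            out = sim.solve_steady_state()
            return out.atp_flux("TOY") if out.converged else -1.0

        grid = np.linspace(0.001, 0.019, 37)
        vals = [flux_at(p) for p in grid]
        best_grid = grid[int(np.argmax(vals))]

        res = maximize_atp_flux(model, "TOY", optimize_phi=["R1", "ATPase"],
                                seed=11, maxiter=300, restarts=2)
        total = res.control.phi["R1"] + res.control.phi["ATPase"]
        assert total == pytest.approx(0.02, rel=1e-3)  # pool cap binds
        assert res.control.phi["R1"] == pytest.approx(best_grid, rel=0.05)
        assert res.j_atp >= max(vals) * 0.999

    def test_trace_is_monotone_and_seed_reproducible(self):
        model = _linear_cell()
        a = maximize_atp_flux(model, "TOY", seed=5, maxiter=80, restarts=1)
        b = maximize_atp_flux(model, "TOY", seed=5, maxiter=80, restarts=1)
        assert a.trace == b.trace
        assert a.j_atp == b.j_atp
        assert all(y >= x for x, y in zip(a.trace, a.trace[1:]))

    def test_different_seeds_agree_on_objective(self):
        model = _linear_cell()
        a = maximize_atp_flux(model, "TOY", seed=1, maxiter=200, restarts=1)
        b = maximize_atp_flux(model, "TOY", seed=2, maxiter=200, restarts=1)
        assert a.j_atp == pytest.approx(b.j_atp, rel=0.01)

    def test_fixture_methane_activator_hits_its_ceiling(self, fixture_model,
                                                        fixture_steady):
        """The methane-activating enzyme is pushed to its 12% bound."""
        res = maximize_atp_flux(fixture_model, "ANME",
                                optimize_phi=["MCR", "FPO", "MTR"],
                                seed=1, maxiter=80, restarts=1,
                                x0_state=fixture_steady)
        assert res.control.phi["MCR"] == pytest.approx(0.12, abs=1e-4)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_infeasible_problem_raises(self):
        model = _linear_cell()
        # reverse the thermodynamics: no positive ATP flux exists
        for r in model.cells["TOY"].reactions:
            r.delta_g0_prime = +40.0
        with pytest.raises(RuntimeError):
            maximize_atp_flux(model, "TOY", seed=0, maxiter=30, restarts=1)


class TestEnergyPartition:
    def test_symmetric_partners_cross_at_half(self):
        model = make_symmetric_consortium()
        front = pareto_energy_partition(
            model, [0.35, 0.45, 0.5, 0.55, 0.65],
            e_donor_mv=-300.0, e_acceptor_mv=-172.0)
        j_a = front["j_atp_A"].to_numpy()
        j_b = front["j_atp_B"].to_numpy()
        # mirror symmetry of the two partners across f_G = 1/2
        assert np.allclose(j_a, j_b[::-1], rtol=1e-4)
        assert crossing_point(front, "j_atp_A", "j_atp_B") == \
            pytest.approx(0.5, abs=0.02)

    def test_zero_allocation_starves_first_partner(self):
        model = make_symmetric_consortium()
        front = pareto_energy_partition(model, [0.0], e_donor_mv=-300.0,
                                        e_acceptor_mv=-172.0)
        assert not front["j_atp_A"].iloc[0] > 1e-6

    def test_empty_grid_rejected(self, fixture_model):
        with pytest.raises(ValueError):
            pareto_energy_partition(fixture_model, [])

    def test_fixture_crossing_reproduces_energy_partition(self, fixture_model):
        """Equal uptake occurs near the carrier potential that allocates
        18.2 kJ/mol to methane oxidation and 20.4 kJ/mol to sulphate
        reduction."""
        front = pareto_energy_partition(fixture_model,
                                        [0.45, 0.5, 0.55, 0.6])
        x = crossing_point(front, "uptake_ANME", "uptake_SRB")
        e = np.interp(x, front["f_g"], front["e_carrier_mv"])
        alloc_rm = 8 * 96.485 * (e - (-259.6)) * 1e-3
        alloc_sr = 8 * 96.485 * ((-209.6) - e) * 1e-3
        assert alloc_rm == pytest.approx(18.2, abs=0.5)
        assert alloc_sr == pytest.approx(20.4, abs=0.5)


class TestCoupling:
    def test_matched_pair_returned_unchanged(self):
        model = make_symmetric_consortium()
        set_diet_potential(model, -236.0)
        a = maximize_atp_flux(model, "A", seed=0, maxiter=60, restarts=1)
        b = maximize_atp_flux(model, "B", seed=0, maxiter=60, restarts=1)
        if abs(a.j_atp - b.j_atp) <= 1e-3 * max(a.j_atp, b.j_atp):
            ra, rb = couple_consortium(model, a, b)
            assert ra is a and rb is b

    def test_unequal_pair_is_rebalanced(self):
        model = make_symmetric_consortium()
        # handicap partner B so A comes out stronger
        from dataclasses import replace
        cb = model.cells["B"]
        cb.enzymes["PUMP"] = replace(cb.enzymes["PUMP"], kcat_fwd=50.0)
        set_diet_potential(model, -236.0)
        a = maximize_atp_flux(model, "A", seed=0, maxiter=60, restarts=1)
        b = maximize_atp_flux(model, "B", seed=0, maxiter=60, restarts=1)
        assert a.j_atp > b.j_atp * 1.01
        ra, rb = couple_consortium(model, a, b, seed=0, maxiter=150)
        assert ra.uptake == pytest.approx(rb.uptake, rel=1e-2)
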