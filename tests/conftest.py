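"""Shared fixtures: the built-in consortium, its steady state and MCA
(computed once per session), and small synthetic single-cell models."""

from __future__ import annotations

import pytest

from aomsr import build_aomsr_model, integrate_to_steady_state
from aomsr.analysis import flux_control_coefficients
from aomsr.model_core import (
    CellModel,
    ConsortiumModel,
    Enzyme,
    Metabolite,
    Reaction,
)


@pytest.fixture(scope="session")
def fixture_model():
    return build_aomsr_model()


@pytest.fixture(scope="session")
def fixture_steady(fixture_model):
    res = integrate_to_steady_state(fixture_model)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def fixture_mca(fixture_model, fixture_steady):
    return {
        cell: flux_control_coefficients(fixture_model, cell,
                                        base=fixture_steady)
        for cell in ("ANME", "SRB")
    }


def _species(sid: str, conc: float, clamped: bool = False,
             compartment: str = "cytoplasm_ANME") -> Metabolite:
    return Metabolite(id=sid, compartment=compartment, concentration=conc,
                      clamped=clamped, composition={"X": 1}, charge=0.0)


def make_chain_model(dg1: float = -3.0, dg2: float = -3.0,
                     closed: bool = True, exchange_k: float = 1.0e3,
                     v1: float = 50.0, v2: float = 50.0) -> ConsortiumModel:
    """Single-cell A <-> B <-> C chain.

    ``closed=True``: no exchange, pools relax to equilibrium.
    ``closed=False``: A is fed from a clamped outer pool and C drains to
    one, giving a flux-carrying steady state.
    """
    mets = {
        "A@RM": _species("A@RM", 1.0e-3),
        "B@RM": _species("B@RM", 1.0e-3),
        "C@RM": _species("C@RM", 1.0e-3),
    }
    reactions = [
        Reaction("R1", {"A@RM": -1, "B@RM": 1}, kind="cytoplasmic",
                 delta_g0_prime=dg1),
        Reaction("R2", {"B@RM": -1, "C@RM": 1}, kind="cytoplasmic",
                 delta_g0_prime=dg2),
    ]
    enzymes = {
        "R1": Enzyme("R1", phi=0.01, phi_max=0.1, kcat_fwd=v1,
                     km_map={"A@RM": 1e-6}, molar_mass=4.752e5),
        "R2": Enzyme("R2", phi=0.01, phi_max=0.1, kcat_fwd=v2,
                     km_map={"B@RM": 1e-6}, molar_mass=4.752e5),
    }
    if not closed:
        mets["A@e"] = _species("A@e", 2.0e-3, clamped=True,
                               compartment="environment")
        mets["C@e"] = _species("C@e", 1.0e-4, clamped=True,
                               compartment="environment")
        reactions.insert(0, Reaction("D_A", {"A@e": -1, "A@RM": 1},
                                     kind="diffusion",
                                     rate_constant=exchange_k))
        reactions.append(Reaction("D_C", {"C@RM": -1, "C@e": 1},
                                  kind="diffusion",
                                  rate_constant=exchange_k))
    cell = CellModel(name="TOY", reactions=reactions, enzymes=enzymes,
                     membrane_potential=0.0, substrate_id="A@e" if not closed
                     else "", atpase_id="",
                     pathway_chi={r.id: 1 for r in reactions})
    return ConsortiumModel(metabolites=mets, cells={"TOY": cell})


def make_pump_cell(e_donor_mv: float, carrier_prefix: str = "T",
                   direction: str = "reduce", name: str = "TOY",
                   nu_plus: float = 1.0, phi: float = 0.01,
                   phi_max: float = 0.1, vcap: float = 100.0,
                   ions_per_atp: int = 6) -> tuple[CellModel,
                                                   dict[str, Metabolite]]:
    """A minimal chemiosmotic cell: one electron-transfer pump feeding the
    shared carrier plus an ATP synthase; used for symmetric-consortium and
    optimizer toys."""
    from aomsr.thermo import delta_g_from_redox

    tox, tred = f"{carrier_prefix}_ox@e", f"{carrier_prefix}_red@e"
    sub, prod = f"S{name}@e", f"P{name}@e"
    mets = {
        sub: _species(sub, 1.0e-3, clamped=True, compartment="environment"),
        prod: _species(prod, 1.0e-3, clamped=True, compartment="environment"),
        f"ATP@{name}": _species(f"ATP@{name}", 1e-2, clamped=True),
        f"ADP@{name}": _species(f"ADP@{name}", 1e-3, clamped=True),
        f"Pi@{name}": _species(f"Pi@{name}", 1e-2, clamped=True),
    }
    if direction == "reduce":
        eq = {sub: -1, tox: -2, prod: 1, tred: 2}
        dg0 = delta_g_from_redox(2, -236.0, e_donor_mv)
    else:
        eq = {sub: -1, tred: -2, prod: 1, tox: 2}
        dg0 = delta_g_from_redox(2, e_donor_mv, -236.0)
    pump = Reaction("PUMP", eq, kind="membrane", delta_g0_prime=dg0,
                    nu_plus=nu_plus, chi_e=1, n_electrons=2)
    atpase = Reaction("ATPase", {f"ADP@{name}": -1, f"Pi@{name}": -1,
                                 f"ATP@{name}": 1},
                      kind="membrane", delta_g0_prime=31.8,
                      nu_plus=-float(ions_per_atp), chi_e=1.0,
                      nu_plus_max=6.5)
    enzymes = {
        "PUMP": Enzyme("PUMP", phi=phi, phi_max=phi_max, kcat_fwd=vcap,
                       km_map={sub: 1e-6}, molar_mass=4.752e5),
        "ATPase": Enzyme("ATPase", phi=phi, phi_max=phi_max, kcat_fwd=vcap,
                         km_map={}, molar_mass=4.752e5),
    }
    cell = CellModel(name=name, reactions=[pump, atpase], enzymes=enzymes,
                     membrane_potential=0.09, ions_per_atp=ions_per_atp,
                     substrate_id=sub, atpase_id="ATPase",
                     pathway_chi={"PUMP": 1})
    return cell, mets


def make_symmetric_consortium() -> ConsortiumModel:
    """Two mirror-image partners exchanging a shared electron carrier whose
    standard potential sits exactly mid-way between donor and acceptor."""
    cell_a, mets_a = make_pump_cell(-300.0, direction="reduce", name="A")
    cell_b, mets_b = make_pump_cell(-172.0, direction="oxidise", name="B")
    mets = {**mets_a, **mets_b}
    mets["T_ox@e"] = _species("T_ox@e", 1e-3, compartment="environment")
    mets["T_red@e"] = _species("T_red@e", 1e-3, compartment="environment")
    return ConsortiumModel(metabolites=mets,
                           cells={"A": cell_a, "B": cell_b},
                           diet_carrier=("T_ox@e", "T_red@e"))
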