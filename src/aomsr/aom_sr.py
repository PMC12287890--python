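"""Built-in consortium network: anaerobic methane oxidation coupled to
sulphate reduction (AOM-SR).

The methane-oxidising archaeon (tag ``RM``, for reverse methanogenesis) runs
the seven-step C1 pathway from methane to bicarbonate plus the
electron-handling membrane complexes (FPO, HDR, RNF), the sodium/proton
antiporter MRP and an ATP synthase.  The sulphate reducer (tag ``SR``) runs
the canonical dissimilatory pathway (SULP, SAT, APR, PPA, DSR, QRC, ADK,
ATP synthase).  The two are linked by direct interspecies electron transfer
through an extracellular tetrahaem cytochrome c3 pool (TpIc3).

Chemical conventions
--------------------
* Reduced membrane electron carriers (MPH2, MQH2, TpIc_red) are tracked as
  electron-only species (formal charge, no protons); the protons they would
  carry are released to the clamped pH pool.  With this convention the
  stoichiometric matrix times the occurrence-number vector reproduces the
  lumped catabolic equations exactly (9 H+ produced per CH4; 10 H+ consumed
  per sulphate once the clamped phosphoryl pool is projected out).
* Standard free energies are pH-7 transformed values; redox steps are
  derived from the standard potentials in ``STANDARD_POTENTIALS_MV`` and the
  two formyl/sulphite closure terms are fixed by Hess's law so pathway sums
  are thermodynamically exact.
* Enzyme capacities (kcat x [E]) are calibrated so that, at the reference
  proteome fractions, a pathway flux near 20 mmol g-1 d-1 reproduces the
  reference per-enzyme thermodynamic drives; kinetic constants for these
  organisms are not individually measurable, so the capacity (not kcat
  itself) is the meaningful default.
"""

from __future__ import annotations

from typing import Mapping

from .model_core import (
    AggregateGeometry,
    CellModel,
    ConsortiumModel,
    Enzyme,
    Metabolite,
    Reaction,
)
from .thermo import delta_g_from_redox

__all__ = [
    "ConfigurationError",
    "DEFAULT_SCENARIO",
    "STANDARD_POTENTIALS_MV",
    "TABLE_REFERENCE",
    "build_aomsr_model",
]


class ConfigurationError(ValueError):
    """A scenario or override block is missing or inconsistent."""


#: Boundary conditions of the reference bioreactor scenario.
DEFAULT_SCENARIO: dict[str, float] = {
    "ph": 7.0,
    "temperature": 298.15,
    "ch4": 0.010,    # mol/kg
    "hco3": 0.010,
    "so4": 0.010,
    "h2s": 0.001,
}

#: Transformed standard reduction potentials (mV) of the redox couples.
STANDARD_POTENTIALS_MV: dict[str, float] = {
    "CH4/HCO3": -259.6,   # 8 e-, equals the operating potential at equal CH4/HCO3
    "SO4/H2S": -217.0,    # 8 e-; gives -209.6 mV at 10 mM sulphate / 1 mM sulphide
    "TpIc3": -236.0,      # extracellular cytochrome c3, 1 e-
    "MP": -165.0,         # methanophenazine, 2 e-
    "F420": -360.0,       # coenzyme F420, 2 e-
    "Fd": -500.0,         # ferredoxin, 1 e-
    "HET": -143.0,        # heterodisulfide CoM-S-S-CoB / HS-CoM + HS-CoB, 2 e-
    "MQ": -74.0,          # menaquinone, 2 e-
    "APS": -60.0,         # APS / AMP + sulphite, 2 e-
}

#: Reference per-enzyme values (proteome fraction %, outward ion
#: translocation per event, occurrence number per pathway turnover,
#: steady-state drive kJ/mol, flux control coefficient) for the calibrated
#: bioreactor state.  These are the published working point of the network
#: and double as the defaults the analysis layer can be run against without
#: re-simulating.
TABLE_REFERENCE: dict[str, dict[str, dict[str, float]]] = {
    "ANME": {
        "MCR": {"phi": 12.0, "nu_plus": 0.0, "chi_e": 1, "f": 1.44, "fcc": 0.44},
        "FPO": {"phi": 4.0, "nu_plus": 1.35, "chi_e": 2, "f": 0.87, "fcc": 0.36},
        "MTR": {"phi": 2.9, "nu_plus": -2.00, "chi_e": 1, "f": 0.46, "fcc": 0.08},
        "MER": {"phi": 1.9, "nu_plus": 0.0, "chi_e": 1, "f": 0.26, "fcc": 0.05},
        "FMD": {"phi": 4.7, "nu_plus": 0.0, "chi_e": 1, "f": 0.17, "fcc": 0.03},
        "FTR": {"phi": 0.2, "nu_plus": 0.0, "chi_e": 1, "f": 0.07, "fcc": 0.01},
        "HDR": {"phi": 1.8, "nu_plus": -2.00, "chi_e": 1, "f": 0.06, "fcc": 0.01},
        "RNF": {"phi": 0.9, "nu_plus": 2.00, "chi_e": 1, "f": 0.05, "fcc": 0.01},
        "MTD": {"phi": 0.1, "nu_plus": 0.0, "chi_e": 1, "f": 0.04, "fcc": 0.01},
        "MCH": {"phi": 0.9, "nu_plus": 0.0, "chi_e": 1, "f": 2.95e-3, "fcc": 0.00},
        "MRP": {"phi": 0.2, "nu_plus": 0.0, "chi_e": 0, "f": 0.0, "fcc": 0.00},
        "ATPase": {"phi": 0.1, "nu_plus": -3.0, "chi_e": 0.234, "f": 10.83,
                   "fcc": float("nan")},
    },
    "SRB": {
        "APR": {"phi": 3.4, "nu_plus": 1.99, "chi_e": 1, "f": 2.87, "fcc": 0.40},
        "PPA": {"phi": 2.8, "nu_plus": 0.96, "chi_e": 1, "f": 2.65, "fcc": 0.39},
        "SULP": {"phi": 0.1, "nu_plus": -0.67, "chi_e": 1, "f": 0.27, "fcc": 0.06},
        "DSR": {"phi": 0.9, "nu_plus": 2.01, "chi_e": 1, "f": 0.69, "fcc": 0.07},
        "QRC": {"phi": 0.9, "nu_plus": 1.16, "chi_e": 4, "f": 0.17, "fcc": 0.07},
        "SAT": {"phi": 7.0, "nu_plus": 0.0, "chi_e": 1, "f": 3.79e-3, "fcc": 0.01},
        "ADK": {"phi": 3.0, "nu_plus": 0.0, "chi_e": 1, "f": 1.66e-3, "fcc": 0.00},
        "ATPase": {"phi": 1.9, "nu_plus": -4.0, "chi_e": 2.235, "f": 0.94,
                   "fcc": float("nan")},
    },
}

# Formal compositions/charges.  Opaque cofactor cores (CoM, CoB, SPT, MF,
# F420, Fd, MP, MQ, TpIc, Ad, P) are conserved moieties; H/O/charge are the
# formal states consistent with the written equations.
_COMPOSITIONS: dict[str, tuple[dict[str, float], float]] = {
    "CH4": ({"C": 1, "H": 4}, 0), "HCO3": ({"C": 1, "H": 1, "O": 3}, -1),
    "SO4": ({"S": 1, "O": 4}, -2), "SO3": ({"S": 1, "O": 3}, -2),
    "H2S": ({"S": 1, "H": 2}, 0), "H2O": ({"H": 2, "O": 1}, 0),
    "H+": ({"H": 1}, 1), "Na+": ({"Na": 1}, 1),
    "CH3SCoM": ({"CoM": 1, "C": 1, "H": 3}, 0), "HSCoM": ({"CoM": 1, "H": 1}, 0),
    "HSCoB": ({"CoB": 1, "H": 1}, 0), "CoMSSCoB": ({"CoM": 1, "CoB": 1}, 0),
    "H4SPT": ({"SPT": 1, "H": 4}, 0),
    "CH3H4SPT": ({"SPT": 1, "C": 1, "H": 6}, 0),
    "CH2H4SPT": ({"SPT": 1, "C": 1, "H": 4}, 0),
    "CHH4SPT": ({"SPT": 1, "C": 1, "H": 3}, 1),
    "CHOH4SPT": ({"SPT": 1, "C": 1, "H": 4, "O": 1}, 0),
    "MF": ({"MF": 1, "H": 1}, 0), "CHOMF": ({"MF": 1, "C": 1, "H": 1, "O": 1}, 0),
    "F420": ({"F420": 1}, 0), "F420H2": ({"F420": 1, "H": 2}, 0),
    "Fd_ox": ({"Fd": 1}, 0), "Fd_red": ({"Fd": 1}, -1),
    "MP": ({"MP": 1}, 0), "MPH2": ({"MP": 1}, -2),
    "MQ": ({"MQ": 1}, 0), "MQH2": ({"MQ": 1}, -2),
    "TpIc_ox": ({"TpIc": 1}, 0), "TpIc_red": ({"TpIc": 1}, -1),
    "ATP": ({"Ad": 1, "P": 3, "O": 10}, -4),
    "ADP": ({"Ad": 1, "P": 2, "O": 7}, -3),
    "AMP": ({"Ad": 1, "P": 1, "O": 4}, -2),
    "Pi": ({"P": 1, "O": 4, "H": 1}, -2),
    "PPi": ({"P": 2, "O": 7, "H": 1}, -3),
    "APS": ({"Ad": 1, "P": 1, "S": 1, "O": 7}, -2),
}

# Reference-state concentrations (mol/kg): the self-consistent steady state
# of the calibrated network under the default scenario, used both as the
# initial condition and as the anchor for the Michaelis constants.
_INITIAL_RM: dict[str, float] = {
    "CH4": 9.980e-3, "HCO3": 1.002e-2, "CH3SCoM": 4.331e-5, "HSCoM": 1.482e-3,
    "HSCoB": 1.964e-4, "CoMSSCoB": 1.435e-3, "H4SPT": 1.350e-3,
    "CH3H4SPT": 2.993e-5, "CH2H4SPT": 3.019e-6, "CHH4SPT": 3.320e-7,
    "CHOH4SPT": 2.710e-7, "MF": 5.004e-4, "CHOMF": 7.990e-8,
    "F420": 4.006e-4, "F420H2": 1.600e-3, "Fd_ox": 9.132e-4,
    "Fd_red": 8.686e-5, "MP": 1.541e-5, "MPH2": 3.987e-3,
}
_INITIAL_SR: dict[str, float] = {
    "SO4": 2.606e-1, "H2S": 1.020e-3, "APS": 3.695e-6, "PPi": 5.233e-6,
    "AMP": 1.001e-4, "SO3": 1.321e-3, "MQ": 2.377e-6, "MQH2": 2.000e-3,
}

# Calibrated capacities (kcat x [E] x saturation at the reference state),
# mmol g^-1 d^-1, chosen as V = chi_e * J* / F_T(f_ref) with J* = 20.
_CAPACITY: dict[str, float] = {
    "MCR": 45.4, "FPO": 248.6, "MTR": 118.1, "MER": 200.9, "FMD": 301.6,
    "FTR": 718.4, "HDR": 836.5, "RNF": 1001.5, "MTD": 1249.4, "MCH": 16822.0,
    "MRP": 10.0, "ATPase_RM": 4.74,
    "APR": 29.2, "PPA": 30.5, "SULP": 193.8, "DSR": 82.4, "QRC": 4700.0,
    "SAT": 13089.0, "ADK": 29880.0, "ATPase_SR": 141.6,
}

_MOLAR_MASS: dict[str, float] = {
    "MCR": 3.0e5, "FPO": 5.5e5, "MTR": 6.7e5, "MER": 9.0e4, "FMD": 2.3e5,
    "FTR": 7.0e4, "HDR": 2.5e5, "RNF": 2.2e5, "MTD": 8.0e4, "MCH": 9.0e4,
    "MRP": 1.2e5, "ATPase": 5.5e5, "APR": 1.7e5, "PPA": 1.0e5, "SULP": 9.0e4,
    "DSR": 2.0e5, "QRC": 1.2e5, "SAT": 1.0e5, "ADK": 5.0e4,
}


def _met(name: str, tag: str, conc: float, clamped: bool = False) -> Metabolite:
    comp, charge = _COMPOSITIONS[name]
    compartment = {
        "e": "environment",
        "RM": "cytoplasm_ANME",
        "SR": "cytoplasm_SRB",
    }[tag]
    return Metabolite(
        id=f"{name}@{tag}" if name != "H2O" else "H2O",
        compartment=compartment, concentration=conc, clamped=clamped,
        composition=comp, charge=charge,
    )


def _reference_delta_g0() -> dict[str, float]:
    """Standard free energies (pH-7 transformed, kJ/mol) per reaction id."""
    e0 = STANDARD_POTENTIALS_MV
    dg = {
        "MCR": 17.0,     # methane activation, reverse of the terminal
        "MTR": 39.4,     # methyl transfer to H4SPT (endergonic as written)
        "MER": 2.0,
        "MTD": 2.0,
        "MCH": 0.5,
        "FTR": 0.5,
        "FPO": delta_g_from_redox(2, e0["MP"], e0["F420"]),
        "HDR": delta_g_from_redox(2, e0["MP"], e0["HET"]),
        "RNF": delta_g_from_redox(2, e0["MP"], e0["Fd"]),
        "DIET": delta_g_from_redox(2, e0["TpIc3"], e0["MP"]),
        "QRC": delta_g_from_redox(2, e0["MQ"], e0["TpIc3"]),
        "APR": delta_g_from_redox(2, e0["APS"], e0["MQ"]),
        "SAT": 46.4,     # sulphate adenylylation
        "PPA": -21.9,    # pyrophosphate hydrolysis
        "ADK": 0.0,
        "SULP": 0.0,
        "MRP": 0.0,
        "ATPase_RM": 31.8,
        "ATPase_SR": 31.8,
    }
    # Hess closure: the formyl-oxidation and sulphite-reduction terms absorb
    # the residuals so that pathway sums equal the lumped redox energies.
    overall_rm = delta_g_from_redox(8, e0["MP"], e0["CH4/HCO3"])
    dg["FMD"] = overall_rm - (
        dg["MCR"] + dg["MTR"] + dg["MER"] + dg["MTD"] + dg["MCH"] + dg["FTR"]
        + dg["HDR"] + 2 * dg["FPO"] + dg["RNF"]
    )
    overall_sr = delta_g_from_redox(8, e0["SO4/H2S"], e0["TpIc3"]) - 2 * 31.8
    dg["DSR"] = overall_sr - (
        dg["SULP"] + dg["SAT"] + dg["PPA"] + dg["APR"] + 4 * dg["QRC"]
        + dg["ADK"]
    )
    return dg


def _anme_reactions(dg: Mapping[str, float], ref: Mapping[str, dict],
                    geometry: AggregateGeometry) -> list[Reaction]:
    t = ref
    return [
        Reaction("MCR", {"CH4@RM": -1, "CoMSSCoB@RM": -1, "CH3SCoM@RM": 1,
                         "HSCoB@RM": 1},
                 kind="cytoplasmic", delta_g0_prime=dg["MCR"],
                 chi_e=t["MCR"]["chi_e"]),
        Reaction("MTR", {"CH3SCoM@RM": -1, "H4SPT@RM": -1, "CH3H4SPT@RM": 1,
                         "HSCoM@RM": 1},
                 kind="membrane", delta_g0_prime=dg["MTR"],
                 nu_plus=t["MTR"]["nu_plus"], ion="Na+",
                 chi_e=t["MTR"]["chi_e"]),
        Reaction("MER", {"CH3H4SPT@RM": -1, "F420@RM": -1, "CH2H4SPT@RM": 1,
                         "F420H2@RM": 1},
                 kind="cytoplasmic", delta_g0_prime=dg["MER"],
                 chi_e=1, n_electrons=2),
        Reaction("MTD", {"CH2H4SPT@RM": -1, "F420@RM": -1, "H+@RM": -1,
                         "CHH4SPT@RM": 1, "F420H2@RM": 1},
                 kind="cytoplasmic", delta_g0_prime=dg["MTD"],
                 chi_e=1, n_electrons=2),
        Reaction("MCH", {"CHH4SPT@RM": -1, "H2O": -1, "CHOH4SPT@RM": 1,
                         "H+@RM": 1},
                 kind="cytoplasmic", delta_g0_prime=dg["MCH"], chi_e=1),
        Reaction("FTR", {"CHOH4SPT@RM": -1, "MF@RM": -1, "CHOMF@RM": 1,
                         "H4SPT@RM": 1},
                 kind="cytoplasmic", delta_g0_prime=dg["FTR"], chi_e=1),
        Reaction("FMD", {"CHOMF@RM": -1, "Fd_ox@RM": -2, "H2O": -2,
                         "MF@RM": 1, "Fd_red@RM": 2, "HCO3@RM": 1, "H+@RM": 3},
                 kind="cytoplasmic", delta_g0_prime=dg["FMD"],
                 chi_e=1, n_electrons=2),
        Reaction("HDR", {"HSCoB@RM": -1, "HSCoM@RM": -1, "MP@RM": -1,
                         "CoMSSCoB@RM": 1, "MPH2@RM": 1, "H+@RM": 2},
                 kind="membrane", delta_g0_prime=dg["HDR"],
                 nu_plus=t["HDR"]["nu_plus"], chi_e=1, n_electrons=2),
        Reaction("FPO", {"F420H2@RM": -1, "MP@RM": -1, "F420@RM": 1,
                         "MPH2@RM": 1, "H+@RM": 2},
                 kind="membrane", delta_g0_prime=dg["FPO"],
                 nu_plus=t["FPO"]["nu_plus"], chi_e=t["FPO"]["chi_e"],
                 n_electrons=2),
        Reaction("RNF", {"Fd_red@RM": -2, "MP@RM": -1, "Fd_ox@RM": 2,
                         "MPH2@RM": 1},
                 kind="membrane", delta_g0_prime=dg["RNF"],
                 nu_plus=t["RNF"]["nu_plus"], ion="Na+", chi_e=1,
                 n_electrons=2),
        Reaction("MRP", {"Na+@RM": -1, "H+@e": -1, "Na+@e": 1, "H+@RM": 1},
                 kind="membrane", delta_g0_prime=0.0, chi_e=0),
        Reaction("ATPase", {"ADP@RM": -1, "Pi@RM": -1, "H+@RM": -1,
                            "ATP@RM": 1, "H2O": 1},
                 kind="membrane", delta_g0_prime=dg["ATPase_RM"],
                 nu_plus=t["ATPase"]["nu_plus"], chi_e=t["ATPase"]["chi_e"],
                 nu_plus_max=4.5),
        Reaction("DIET", {"MPH2@RM": -1, "TpIc_ox@e": -2, "MP@RM": 1,
                          "TpIc_red@e": 2},
                 kind="exchange", delta_g0_prime=dg["DIET"], chi_e=4,
                 n_electrons=2, rate_constant=1.0e5),
        Reaction("D_CH4", {"CH4@e": -1, "CH4@RM": 1}, kind="diffusion",
                 chi_e=1, rate_constant=geometry.mass_transfer["CH4"]),
        Reaction("D_HCO3", {"HCO3@RM": -1, "HCO3@e": 1}, kind="diffusion",
                 chi_e=1, rate_constant=geometry.mass_transfer["HCO3"]),
    ]


def _srb_reactions(dg: Mapping[str, float], ref: Mapping[str, dict],
                   geometry: AggregateGeometry) -> list[Reaction]:
    t = ref
    return [
        Reaction("SULP", {"SO4@e": -1, "SO4@SR": 1}, kind="membrane",
                 delta_g0_prime=dg["SULP"], nu_plus=t["SULP"]["nu_plus"],
                 chi_e=1),
        Reaction("SAT", {"SO4@SR": -1, "ATP@SR": -1, "H+@SR": -1,
                         "APS@SR": 1, "PPi@SR": 1},
                 kind="cytoplasmic", delta_g0_prime=dg["SAT"], chi_e=1),
        Reaction("PPA", {"PPi@SR": -1, "H2O": -1, "Pi@SR": 2, "H+@SR": 1},
                 kind="membrane", delta_g0_prime=dg["PPA"],
                 nu_plus=t["PPA"]["nu_plus"], chi_e=1),
        Reaction("APR", {"APS@SR": -1, "MQH2@SR": -1, "AMP@SR": 1,
                         "SO3@SR": 1, "MQ@SR": 1},
                 kind="membrane", delta_g0_prime=dg["APR"],
                 nu_plus=t["APR"]["nu_plus"], chi_e=1, n_electrons=2),
        Reaction("DSR", {"SO3@SR": -1, "MQH2@SR": -3, "H+@SR": -8,
                         "H2S@SR": 1, "MQ@SR": 3, "H2O": 3},
                 kind="membrane", delta_g0_prime=dg["DSR"],
                 nu_plus=t["DSR"]["nu_plus"], chi_e=1, n_electrons=6,
                 nu_plus_max=6.0),
        Reaction("QRC", {"TpIc_red@e": -2, "MQ@SR": -1, "TpIc_ox@e": 2,
                         "MQH2@SR": 1},
                 kind="membrane", delta_g0_prime=dg["QRC"],
                 nu_plus=t["QRC"]["nu_plus"], chi_e=t["QRC"]["chi_e"],
                 n_electrons=2),
        Reaction("ADK", {"AMP@SR": -1, "ATP@SR": -1, "ADP@SR": 2},
                 kind="cytoplasmic", delta_g0_prime=dg["ADK"], chi_e=1),
        Reaction("ATPase", {"ADP@SR": -1, "Pi@SR": -1, "H+@SR": -1,
                            "ATP@SR": 1, "H2O": 1},
                 kind="membrane", delta_g0_prime=dg["ATPase_SR"],
                 nu_plus=t["ATPase"]["nu_plus"], chi_e=t["ATPase"]["chi_e"],
                 nu_plus_max=4.5),
        Reaction("D_H2S", {"H2S@SR": -1, "H2S@e": 1}, kind="diffusion",
                 chi_e=1, rate_constant=geometry.mass_transfer["H2S"]),
    ]


def _make_enzymes(cell_tag: str, reactions: list[Reaction],
                  ref: Mapping[str, dict], conc: Mapping[str, float],
                  protein_per_gdw: float = 0.55) -> dict[str, Enzyme]:
    """Build enzymes with kcat back-calculated from calibrated capacities."""
    enzymes: dict[str, Enzyme] = {}
    for rxn in reactions:
        if rxn.id not in ref:
            continue  # diffusion / exchange steps carry no enzyme
        phi = ref[rxn.id]["phi"] / 100.0
        km_map = {}
        for sid in rxn.substrates:
            base = sid.split("@")[0]
            if base in ("H+", "H2O"):
                continue
            km_map[sid] = max(conc[sid] / 20.0, 1e-9)
        sat = 1.0
        for sid, km in km_map.items():
            sat *= conc[sid] / (conc[sid] + km)
        cap_key = f"{rxn.id}_{cell_tag}" if rxn.id == "ATPase" else rxn.id
        mm = _MOLAR_MASS[rxn.id if rxn.id != "ATPase" else "ATPase"]
        e_conc = phi * protein_per_gdw / mm  # mol per g dw
        kcat = _CAPACITY[cap_key] / (e_conc * 86400.0 * 1e3 * sat)
        phi_max = 0.12 if rxn.id == "MCR" else max(0.10, phi * 1.2)
        enzymes[rxn.id] = Enzyme(
            reaction_id=rxn.id, phi=phi, phi_max=phi_max, kcat_fwd=kcat,
            km_map=km_map, molar_mass=mm,
        )
    return enzymes


def build_aomsr_model(scenario: Mapping[str, float] | None = None,
                      overrides: Mapping[str, Mapping[str, float]] | None = None,
                      ) -> ConsortiumModel:
    """Construct the built-in AOM-SR consortium model.

    Parameters
    ----------
    scenario : mapping, optional
        Boundary conditions; must contain ``ph``, ``temperature``, ``ch4``,
        ``hco3``, ``so4`` and ``h2s`` (missing keys raise
        :class:`ConfigurationError`).  Defaults to the reference bioreactor
        scenario (pH 7, 10 mM methane/bicarbonate/sulphate, 1 mM sulphide).
    overrides : mapping, optional
        ``{"phi": {...}, "nu_plus": {...}}`` blocks keyed by
        ``CELL.REACTION`` (e.g. ``"ANME.FPO"``) applied after construction.
    """
    scen = dict(DEFAULT_SCENARIO)
    if scenario is not None:
        scen.update(scenario)
    for key in DEFAULT_SCENARIO:
        if scen.get(key) is None:
            raise ConfigurationError(f"scenario is missing required entry {key!r}")
    for key in ("ch4", "hco3", "so4", "h2s"):
        if scen[key] <= 0:
            raise ConfigurationError(f"scenario entry {key!r} must be positive")

    geometry = AggregateGeometry()
    dg = _reference_delta_g0()

    mets: dict[str, Metabolite] = {}

    def add(m: Metabolite) -> None:
        mets[m.id] = m

    # Environment (boundary species clamped; the DIET carrier pool floats).
    add(_met("CH4", "e", scen["ch4"], clamped=True))
    add(_met("HCO3", "e", scen["hco3"], clamped=True))
    add(_met("SO4", "e", scen["so4"], clamped=True))
    add(_met("H2S", "e", scen["h2s"], clamped=True))
    add(_met("H+", "e", 10.0 ** (-scen["ph"]), clamped=True))
    add(_met("Na+", "e", 1.0e-2, clamped=True))
    add(_met("TpIc_ox", "e", 9.937e-4))
    add(_met("TpIc_red", "e", 1.007e-3))
    add(Metabolite("H2O", "environment", 1.0, clamped=True,
                   composition=_COMPOSITIONS["H2O"][0], charge=0.0))

    for name, c in _INITIAL_RM.items():
        add(_met(name, "RM", c))
    for name, c in _INITIAL_SR.items():
        add(_met(name, "SR", c))
    for tag in ("RM", "SR"):
        add(_met("ATP", tag, 1.0e-2, clamped=True))
        add(_met("ADP", tag, 1.0e-3, clamped=True))
        add(_met("Pi", tag, 1.0e-2, clamped=True))
        add(_met("H+", tag, 10.0 ** (-scen["ph"]), clamped=True))
    add(_met("Na+", "RM", 1.0e-2, clamped=True))

    conc = {sid: m.concentration for sid, m in mets.items()}

    rm_reactions = _anme_reactions(dg, TABLE_REFERENCE["ANME"], geometry)
    sr_reactions = _srb_reactions(dg, TABLE_REFERENCE["SRB"], geometry)

    anme = CellModel(
        name="ANME",
        reactions=rm_reactions,
        enzymes=_make_enzymes("RM", rm_reactions, TABLE_REFERENCE["ANME"], conc),
        membrane_potential=0.2029,
        ions_per_atp=3,
        substrate_id="CH4@e",
        atpase_id="ATPase",
        pathway_chi={
            "MCR": 1, "MTR": 1, "MER": 1, "MTD": 1, "MCH": 1, "FTR": 1,
            "FMD": 1, "HDR": 1, "FPO": 2, "RNF": 1, "D_CH4": 1, "D_HCO3": 1,
        },
    )
    srb = CellModel(
        name="SRB",
        reactions=sr_reactions,
        enzymes=_make_enzymes("SR", sr_reactions, TABLE_REFERENCE["SRB"], conc),
        membrane_potential=0.1292,
        ions_per_atp=4,
        substrate_id="SO4@e",
        atpase_id="ATPase",
        pathway_chi={
            "SULP": 1, "SAT": 1, "PPA": 1, "APR": 1, "DSR": 1, "QRC": 4,
            "ADK": 1, "D_H2S": 1,
        },
    )

    model = ConsortiumModel(
        metabolites=mets,
        cells={"ANME": anme, "SRB": srb},
        geometry=geometry,
        temperature=scen["temperature"],
        ph=scen["ph"],
    )

    if overrides:
        _apply_overrides(model, overrides)
    return model


def _apply_overrides(model: ConsortiumModel,
                     overrides: Mapping[str, Mapping[str, float]]) -> None:
    from dataclasses import replace

    for key, value in overrides.get("phi", {}).items():
        cell_name, rid = key.split(".")
        cell = model.cells[cell_name]
        cell.enzymes[rid] = replace(cell.enzymes[rid], phi=float(value))
    for key, value in overrides.get("nu_plus", {}).items():
        cell_name, rid = key.split(".")
        cell = model.cells[cell_name]
        rxn = cell.reaction(rid)
        rxn.nu_plus = float(value)
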