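"""Domain types for two-member chemiosmotic consortium models.

A :class:`ConsortiumModel` holds two :class:`CellModel` compartments (an
archaeal methane oxidiser and a sulphate-reducing bacterium in the built-in
network), an environment pool, diffusive exchange steps and a shared
extracellular electron carrier (DIET).  Species carry formal elemental
compositions and charges so the network can be audited; reactions carry the
chemiosmotic bookkeeping (ion translocation stoichiometry ``nu_plus``,
occurrence number ``chi_e``) used throughout the thermodynamic and
bioenergetic analyses.

Species ids are ``NAME@TAG`` where TAG is ``e`` (environment), ``RM``
(methane-oxidising cell) or ``SR`` (sulphate reducer); ``H2O`` is global.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "Enzyme",
    "CellModel",
    "AggregateGeometry",
    "ConsortiumModel",
    "ValidationReport",
    "validate_network",
    "stoichiometric_matrix",
    "pathway_net_equation",
]

COMPARTMENTS = (
    "environment",
    "cytoplasm_ANME",
    "cytoplasm_SRB",
    "membrane_ANME",
    "membrane_SRB",
)


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``composition`` maps element / moiety symbols (C, H, O, S, plus opaque
    cofactor cores such as CoM, SPT, MP) to counts; ``charge`` is the formal
    charge consistent with the written reaction equations.  Concentrations
    are molal (mol per kg water, numerically equal to mol/L here).
    """

    id: str
    compartment: str
    concentration: float
    clamped: bool = False
    composition: Mapping[str, float] = field(default_factory=dict)
    charge: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"{self.id}: concentration must be positive")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"{self.id}: unknown compartment {self.compartment!r}")


@dataclass
class Reaction:
    """A reaction or transport step.

    ``equation`` maps species ids to signed stoichiometric coefficients
    (negative = consumed).  ``nu_plus`` is the number of ions translocated
    *outward* across the membrane per reaction event (negative = inward);
    ``chi_e`` is the number of times the step occurs per pathway turnover.
    ``delta_g0_prime`` is the pH-7 transformed standard free energy of the
    written equation, kJ/mol.  ``rate_constant`` is used by non-enzymatic
    steps (diffusion: mmol g^-1 d^-1 per mol/kg gradient; exchange: a
    capacity in mmol g^-1 d^-1).
    """

    id: str
    equation: Mapping[str, float]
    kind: str = "cytoplasmic"  # cytoplasmic | membrane | diffusion | exchange
    delta_g0_prime: float = 0.0
    nu_plus: float = 0.0
    ion: str = "H+"
    chi_e: float = 1.0
    n_electrons: int = 0
    rate_constant: float | None = None
    nu_plus_max: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("cytoplasmic", "membrane", "diffusion", "exchange"):
            raise ValueError(f"{self.id}: unknown reaction kind {self.kind!r}")
        if self.chi_e < 0:
            raise ValueError(f"{self.id}: chi_e must be non-negative")

    @property
    def substrates(self) -> list[str]:
        return [s for s, nu in self.equation.items() if nu < 0]

    @property
    def products(self) -> list[str]:
        return [s for s, nu in self.equation.items() if nu > 0]


@dataclass
class Enzyme:
    """Kinetic parameters and proteome allocation of one enzyme.

    ``phi`` is the proteome mass fraction (0..1), bounded by ``phi_max``;
    ``km_map`` gives Michaelis constants (mol/kg) per substrate id.
    """

    reaction_id: str
    phi: float
    phi_max: float = 1.0
    kcat_fwd: float = 10.0  # s^-1
    km_map: Mapping[str, float] = field(default_factory=dict)
    molar_mass: float = 2.0e5  # g/mol

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError(f"{self.reaction_id}: phi outside [0, 1]")
        if self.phi_max <= 0 or self.phi_max > 1:
            raise ValueError(f"{self.reaction_id}: phi_max outside (0, 1]")

    def concentration(self, protein_per_gdw: float = 0.55) -> float:
        """Enzyme concentration in mol per g dry weight."""
        return self.phi * protein_per_gdw / self.molar_mass

    def vmax(self, protein_per_gdw: float = 0.55) -> float:
        """Capacity kcat*[E] in mmol g^-1 d^-1."""
        return self.kcat_fwd * self.concentration(protein_per_gdw) * 86400.0 * 1e3


@dataclass
class AggregateGeometry:
    """Shell-type aggregate geometry used for diffusive exchange.

    ``mass_transfer`` holds effective biomass-specific mass-transfer
    coefficients (mmol g^-1 d^-1 per mol/kg of gradient) for each exchanged
    species; they are dominated by cell-envelope permeation, not aqueous
    diffusion, so at the default 4 um diameter exchange is never limiting
    and the methane:sulphate biomass-specific uptake capacity ratio is 1.
    """

    diameter: float = 4e-6  # m
    architecture: str = "shell"
    cell_density: float = 5.0e4  # g dry weight per m^3 aggregate
    mass_transfer: Mapping[str, float] = field(
        default_factory=lambda: {"CH4": 1.0e6, "HCO3": 1.0e6, "H2S": 1.0e6}
    )

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("aggregate diameter must be positive")

    def uptake_flux_ratio(self) -> float:
        """Methane : sulphate biomass-specific uptake capacity ratio."""
        return self.mass_transfer["CH4"] / self.mass_transfer.get(
            "SO4", self.mass_transfer["CH4"]
        )


@dataclass
class CellModel:
    """One consortium member: its reactions, enzymes and membrane state."""

    name: str  # "ANME" | "SRB"
    reactions: list[Reaction]
    enzymes: dict[str, Enzyme]
    membrane_potential: float = 0.15  # V
    membrane_capacitance: float = 0.03  # C V^-1 per g dry weight
    ions_per_atp: int = 3
    substrate_id: str = ""
    atpase_id: str = ""
    pathway_chi: Mapping[str, float] = field(default_factory=dict)
    membrane_pool_cap: float = 0.20
    cytoplasm_pool_cap: float = 0.40
    protein_per_gdw: float = 0.55

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"{self.name}: no reaction {rid!r}")

    @property
    def enzymatic_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.id in self.enzymes]

    def membrane_phi_total(self) -> float:
        return sum(
            e.phi for rid, e in self.enzymes.items()
            if self.reaction(rid).kind == "membrane"
        )

    def cytoplasm_phi_total(self) -> float:
        return sum(
            e.phi for rid, e in self.enzymes.items()
            if self.reaction(rid).kind == "cytoplasmic"
        )


@dataclass
class ConsortiumModel:
    """The full two-member model plus environment and DIET coupling."""

    metabolites: dict[str, Metabolite]
    cells: dict[str, CellModel]
    geometry: AggregateGeometry = field(default_factory=AggregateGeometry)
    diet_carrier: tuple[str, str] = ("TpIc_ox@e", "TpIc_red@e")
    f_g: float = 0.5
    temperature: float = 298.15
    ph: float = 7.0
    cell_water: float = 2.0e-3  # kg cell water per g dry weight

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_g <= 1.0):
            raise ValueError("f_g must lie in [0, 1]")

    def metabolite(self, sid: str) -> Metabolite:
        return self.metabolites[sid]

    @property
    def all_reactions(self) -> list[tuple[str, Reaction]]:
        out: list[tuple[str, Reaction]] = []
        for cname, cell in self.cells.items():
            out.extend((cname, r) for r in cell.reactions)
        return out

    def copy(self) -> "ConsortiumModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Network auditing
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _balance_violation(model: ConsortiumModel, rxn: Reaction) -> str | None:
    """Check element/charge balance of a reaction up to implicit H2O / H+.

    Both water (activity 1) and protons (clamped pH) may be absorbed
    implicitly, so the audited invariants are: every element other than H
    and O balances exactly, O balances up to added water, and the parity
    quantity charge - n_H + 2*n_O is conserved (adding H2O or H+ leaves it
    unchanged; losing a single H from an equation breaks it).
    """
    elements: dict[str, float] = {}
    d_charge = 0.0
    for sid, nu in rxn.equation.items():
        if sid == "H2O":
            continue
        met = model.metabolites.get(sid)
        if met is None:
            return f"{rxn.id}: unknown species {sid!r}"
        for el, n in met.composition.items():
            elements[el] = elements.get(el, 0.0) + nu * n
        d_charge += nu * met.charge
    d_h = elements.pop("H", 0.0)
    d_o = elements.pop("O", 0.0)
    bad = {el: d for el, d in elements.items() if abs(d) > 1e-9}
    if bad:
        return f"{rxn.id}: element imbalance {bad}"
    parity = d_charge - d_h + 2.0 * d_o
    if abs(parity) > 1e-9:
        return (
            f"{rxn.id}: charge/H/O imbalance (residual {parity:+.3g} after "
            "implicit H2O/H+)"
        )
    return None


def validate_network(model: ConsortiumModel) -> ValidationReport:
    """Audit a consortium model: balances, proteome bounds, orphans."""
    report = ValidationReport()
    used: set[str] = set()
    for cname, cell in model.cells.items():
        for rxn in cell.reactions:
            used.update(rxn.equation)
            if rxn.kind != "diffusion":
                msg = _balance_violation(model, rxn)
                if msg:
                    report.violations.append(f"{cname}/{msg}")
            else:
                for sid in rxn.equation:
                    if sid not in model.metabolites:
                        report.violations.append(
                            f"{cname}/{rxn.id}: unknown species {sid!r}"
                        )
        for rxn in cell.reactions:
            if rxn.id != cell.atpase_id and abs(rxn.nu_plus) > rxn.nu_plus_max + 1e-9:
                report.violations.append(
                    f"{cname}/{rxn.id}: |nu_plus| = {abs(rxn.nu_plus):.2f} exceeds "
                    f"bound {rxn.nu_plus_max:.2f}"
                )
        for rid, enz in cell.enzymes.items():
            if enz.phi > enz.phi_max + 1e-12:
                report.violations.append(
                    f"{cname}/{rid}: phi = {enz.phi:.4f} exceeds phi_max = "
                    f"{enz.phi_max:.2f}"
                )
        if cell.membrane_phi_total() > cell.membrane_pool_cap + 1e-12:
            report.violations.append(
                f"{cname}: membrane proteome pool exceeds cap "
                f"{cell.membrane_pool_cap:.2f}"
            )
        if cell.cytoplasm_phi_total() > cell.cytoplasm_pool_cap + 1e-12:
            report.violations.append(
                f"{cname}: cytoplasmic proteome pool exceeds cap "
                f"{cell.cytoplasm_pool_cap:.2f}"
            )
    for sid in model.metabolites:
        if sid not in used and sid != "H2O":
            report.warnings.append(f"orphan metabolite {sid!r}")
    return report


# ---------------------------------------------------------------------------
# Stoichiometry
# ---------------------------------------------------------------------------

def stoichiometric_matrix(cell: CellModel, species: Iterable[str] | None = None
                          ) -> pd.DataFrame:
    """Signed stoichiometric matrix (species x reactions) of one cell."""
    if species is None:
        seen: dict[str, None] = {}
        for rxn in cell.reactions:
            for sid in rxn.equation:
                seen.setdefault(sid)
        species = list(seen)
    mat = pd.DataFrame(
        0.0, index=list(species), columns=[r.id for r in cell.reactions]
    )
    for rxn in cell.reactions:
        for sid, nu in rxn.equation.items():
            if sid not in mat.index:
                raise KeyError(f"unknown species {sid!r} in {rxn.id}")
            mat.loc[sid, rxn.id] = nu
    return mat


def pathway_net_equation(cell: CellModel, eliminate_phosphates: bool = True
                         ) -> dict[str, float]:
    """Net pathway equation: stoichiometric matrix x occurrence vector.

    Uses ``cell.pathway_chi`` (the catabolic core; ATP synthase and
    carrier-exchange steps excluded).  With ``eliminate_phosphates`` the
    clamped ATP/ADP/Pi turnover is projected out through the ATP synthase
    stoichiometry, which is how the lumped catabolic equations are
    conventionally written.
    """
    net: dict[str, float] = {}

    def add(eq: Mapping[str, float], w: float) -> None:
        for sid, nu in eq.items():
            net[sid] = net.get(sid, 0.0) + w * nu

    for rid, chi in cell.pathway_chi.items():
        add(cell.reaction(rid).equation, chi)
    if eliminate_phosphates and cell.atpase_id:
        atpase = cell.reaction(cell.atpase_id)
        atp_id = next(s for s in atpase.equation if s.startswith("ATP"))
        deficit = -net.get(atp_id, 0.0)
        if abs(deficit) > 1e-12:
            add(atpase.equation, deficit / atpase.equation[atp_id])
    return {s: round(v, 9) for s, v in net.items() if abs(v) > 1e-9}


def scale_phi(cell: CellModel, rid: str, factor: float) -> None:
    """In-place multiplicative perturbation of one enzyme's proteome share."""
    enz = cell.enzymes[rid]
    cell.enzymes[rid] = replace(enz, phi=enz.phi * factor, phi_max=max(
        enz.phi_max, enz.phi * factor))
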