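"""Free-energy engine for chemiosmotic metabolic networks.

Implements reaction quotients, equilibrium constants, the chemiosmotic free
energy change

    dG_i = RT ln(Q_i / K_i) + nu+_i * F * dpsi,

Nernst potentials of redox couples, phosphorylation energy, and the
thermodynamic potential factor

    F_T = 1 - exp(-f / (chi * R * T)),

where ``f`` is the thermodynamic drive (the negative free-energy change of a
lumped step, kJ/mol) and ``chi`` the average stoichiometric number.  All free
energies are in kJ/mol, potentials in volts unless a function says otherwise.

Conventions
-----------
* Standard free energies (``delta_g0_prime``) are pH-7 transformed values.
  Internally they are converted to the untransformed equilibrium constant so
  that reaction quotients may carry H+ explicitly at its clamped activity
  (``10**-pH``).  Water activity is fixed at 1 and never enters a quotient.
* ``nu_plus > 0`` means ions translocated *outward*; outward translocation
  against the membrane potential adds a positive electrical cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "R_KJ",
    "F_KJ",
    "ThermoContext",
    "RedoxCouple",
    "DriveSummary",
    "reaction_quotient",
    "equilibrium_constant",
    "delta_g",
    "delta_g_from_redox",
    "nernst_potential",
    "phosphorylation_energy",
    "thermodynamic_potential_factor",
]

#: Gas constant, kJ mol^-1 K^-1.
R_KJ = 8.3145e-3
#: Faraday constant, kJ V^-1 mol^-1 (equivalently C mmol^-1... it is 96485 C/mol).
F_KJ = 96.485


@dataclass(frozen=True)
class ThermoContext:
    """Physical constants and conditions shared by all thermodynamic calls.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.  Default 298.15 K (25 C, the
        standard-state convention used throughout).
    ph : float
        The clamped pH; protons enter reaction quotients at ``10**-ph``.
    """

    temperature: float = 298.15
    ph: float = 7.0
    R: float = R_KJ
    F: float = F_KJ

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def rt(self) -> float:
        """R*T in kJ/mol."""
        return self.R * self.temperature

    @property
    def proton_activity(self) -> float:
        return 10.0 ** (-self.ph)


@dataclass(frozen=True)
class RedoxCouple:
    """A half reaction ``ox + n e- -> red`` with a standard potential in mV."""

    id: str
    oxidised: str
    reduced: str
    standard_potential_mv: float
    n_electrons: int = 1
    stoichiometry: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")


@dataclass(frozen=True)
class DriveSummary:
    """Lumped-pathway drive bookkeeping: drive f (kJ/mol), chi and F_T.

    ``feasible`` is False when the drive is non-positive, in which case F_T
    is <= 0 and the pathway cannot run forward.
    """

    f: float
    chi: float
    f_t: float

    @property
    def feasible(self) -> bool:
        return self.f > 0.0


def reaction_quotient(reaction, state, ctx: ThermoContext | None = None) -> float:
    """Reaction quotient Q = prod(products^nu) / prod(substrates^nu).

    ``reaction`` needs an ``equation`` mapping of species id -> signed
    stoichiometry; ``state`` needs a ``concentration(species_id)`` method (a
    :class:`~aomsr.kinetics.SystemState`).  Clamped H+ enters at ``10**-pH``;
    water is excluded (activity 1).
    """
    ctx = ctx or ThermoContext()
    log_q = 0.0
    for species, nu in reaction.equation.items():
        base = species.split("@")[0]
        if base == "H2O":
            continue
        if base in ("H+", "H"):
            conc = ctx.proton_activity
        else:
            conc = state.concentration(species)
            if conc <= 0:
                raise ValueError(
                    f"non-positive concentration for {species!r} in quotient of "
                    f"{reaction.id!r}"
                )
        log_q += nu * math.log(conc)
    return math.exp(log_q)


def equilibrium_constant(reaction, ctx: ThermoContext | None = None) -> float:
    """Untransformed K consistent with quotients that carry H+ explicitly.

    ``delta_g0_prime`` is the pH-7 transformed standard free energy for the
    written equation; K is shifted by ``1e-7**dH`` (dH = net H+ produced) so
    that ``RT ln(Q/K)`` with explicit protons reproduces the transformed
    convention exactly.
    """
    ctx = ctx or ThermoContext()
    dh = sum(
        nu for sp, nu in reaction.equation.items() if sp.split("@")[0] in ("H+", "H")
    )
    log_k = -reaction.delta_g0_prime / ctx.rt + dh * math.log(1e-7)
    return math.exp(log_k)


def delta_g(reaction, state, delta_psi: float = 0.0,
            ctx: ThermoContext | None = None) -> float:
    """Chemiosmotic free energy change, kJ/mol.

    dG = RT ln(Q/K) + nu+ F dpsi.  ``delta_psi`` in volts; positive
    ``nu_plus`` (outward translocation) adds a positive electrical cost.
    """
    ctx = ctx or ThermoContext()
    q = reaction_quotient(reaction, state, ctx)
    k = equilibrium_constant(reaction, ctx)
    nu_plus = getattr(reaction, "nu_plus", 0.0) or 0.0
    return ctx.rt * math.log(q / k) + nu_plus * ctx.F * delta_psi


def delta_g_chemical(reaction, state, ctx: ThermoContext | None = None) -> float:
    """The RT ln(Q/K) part of dG only (no electrical term), kJ/mol."""
    ctx = ctx or ThermoContext()
    q = reaction_quotient(reaction, state, ctx)
    k = equilibrium_constant(reaction, ctx)
    return ctx.rt * math.log(q / k)


def delta_g_from_redox(n_electrons: int, e_acceptor_mv: float, e_donor_mv: float,
                       ctx: ThermoContext | None = None) -> float:
    """dG = -n F (E_A - E_D), potentials in mV, result in kJ/mol."""
    if n_electrons < 1:
        raise ValueError("n_electrons must be >= 1")
    ctx = ctx or ThermoContext()
    return -n_electrons * ctx.F * (e_acceptor_mv - e_donor_mv) * 1e-3


def nernst_potential(couple: RedoxCouple, state, ctx: ThermoContext | None = None) -> float:
    """Actual reduction potential of a couple, in mV.

    E = E0 - (RT/nF) ln([red]/[ox]), the per-couple (not per-electron-pair)
    convention: n is the couple's electron number.
    """
    ctx = ctx or ThermoContext()
    red = state.concentration(couple.reduced)
    ox = state.concentration(couple.oxidised)
    if red <= 0 or ox <= 0:
        raise ValueError(f"non-positive concentration in couple {couple.id!r}")
    return couple.standard_potential_mv - (
        ctx.rt / (couple.n_electrons * ctx.F)
    ) * math.log(red / ox) * 1e3


def phosphorylation_energy(atp: float, adp: float, pi: float,
                           delta_g0_atp: float = 31.8,
                           ctx: ThermoContext | None = None) -> float:
    """Free energy of ADP + Pi -> ATP at the given concentrations, kJ/mol.

    With the clamped 10 mM ATP, 1 mM ADP and 10 mM Pi and the default
    transformed standard value of +31.8 kJ/mol this evaluates to
    31.8 + RT ln(1000) = 48.9 kJ per mol ATP.
    """
    ctx = ctx or ThermoContext()
    for name, c in (("atp", atp), ("adp", adp), ("pi", pi)):
        if c <= 0:
            raise ValueError(f"{name} concentration must be positive")
    return delta_g0_atp + ctx.rt * math.log(atp / (adp * pi))


def thermodynamic_potential_factor(f: float, chi: float,
                                   ctx: ThermoContext | None = None) -> float:
    """F_T = 1 - exp(-f / (chi R T)).

    ``f`` is the thermodynamic drive (positive for a favourable step).  The
    result lies in (0, 1) for positive drives, is 0 at equilibrium and
    negative (infeasible) for f < 0.
    """
    if chi <= 0:
        raise ValueError("chi must be positive")
    ctx = ctx or ThermoContext()
    return -math.expm1(-f / (chi * ctx.rt))


def drive_summary(f: float, chi: float, ctx: ThermoContext | None = None) -> DriveSummary:
    """Bundle a drive with its chi and thermodynamic potential factor."""
    return DriveSummary(f=f, chi=chi, f_t=thermodynamic_potential_factor(f, chi, ctx))
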