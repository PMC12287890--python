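"""Metabolic control analysis and bioenergetic bookkeeping.

Flux control coefficients are computed by finite-difference perturbation of
proteome fractions with a full re-solve of the steady state,

    FCC_i = d ln J / d ln phi_i,

and the ledger assembles the pathway-level energetics: net charge
translocation, ATP yield, thermodynamic efficiency, return on investment,
thermodynamic drive, average stoichiometric number and the thermodynamic
potential factor — the machine-readable twin of the headline summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .kinetics import Simulator, SteadyStateResult
from .model_core import CellModel, ConsortiumModel
from .thermo import F_KJ, ThermoContext, phosphorylation_energy, \
    thermodynamic_potential_factor

__all__ = [
    "MCAResult",
    "BioenergeticLedger",
    "CellLedger",
    "flux_control_coefficients",
    "average_stoichiometric_number",
    "net_charge_translocation",
    "atp_yield",
    "thermodynamic_efficiency",
    "roi",
    "biomass_yield",
    "drive_fcc_correlation",
    "bioenergetic_report",
]


@dataclass
class MCAResult:
    """Flux control coefficients of one cell's pathway flux."""

    cell: str
    flux_id: str
    base_flux: float
    fcc: dict[str, float]
    perturbation: float
    missing: list[str] = field(default_factory=list)

    @property
    def total(self) -> float:
        """Summation-theorem check: sum of FCCs over the cell's enzymes."""
        return float(sum(self.fcc.values()))

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.fcc.items(), key=lambda kv: -kv[1])


def flux_control_coefficients(model: ConsortiumModel, cell: str,
                              base: SteadyStateResult | None = None,
                              rel_perturbation: float = 0.01,
                              flux_id: str | None = None) -> MCAResult:
    """Central-difference FCCs with a steady-state re-solve per perturbation.

    Control is analysed on the cell's own submodel: the partner interface
    (the shared electron-carrier pool) is clamped and the membrane potential
    held at its steady-state value, so each pathway is judged against its
    fixed energy budget.  The ATP synthase is excluded (with the adenylate
    pool clamped, ATP synthesis is at steady state and its abundance holds
    no pathway control).  Perturbed problems are warm-started from the base
    solution; a perturbation whose steady state cannot be recovered is
    reported in ``missing`` rather than set to zero.
    """
    sim = Simulator(model)
    if base is None:
        base = sim.solve_steady_state()
    if not base.converged:
        raise RuntimeError("base steady state did not converge")
    cellobj = model.cells[cell]
    if flux_id is None:
        flux_id = base.uptake_reactions.get(cell)
    if flux_id is None or (cell, flux_id) not in base.fluxes:
        raise ValueError(f"no uptake flux identified for cell {cell!r}")
    j0 = base.fluxes[(cell, flux_id)]

    fcc: dict[str, float] = {}
    missing: list[str] = []
    d = math.log(1.0 + rel_perturbation) - math.log(1.0 - rel_perturbation)
    for rid in cellobj.enzymes:
        if rid == cellobj.atpase_id:
            continue
        lnj = []
        ok = True
        for factor in (1.0 + rel_perturbation, 1.0 - rel_perturbation):
            pert = model.copy()
            pcell = pert.cells[cell]
            enz = pcell.enzymes[rid]
            from dataclasses import replace
            pcell.enzymes[rid] = replace(
                enz, phi=enz.phi * factor,
                phi_max=max(enz.phi_max, enz.phi * factor))
            psim = Simulator(pert, active_cells=[cell],
                             clamp_species=model.diet_carrier,
                             freeze_psi=True)
            res = psim.refine_from(base.state)
            if not res.converged or res.fluxes[(cell, flux_id)] <= 0:
                ok = False
                break
            lnj.append(math.log(res.fluxes[(cell, flux_id)]))
        if not ok:
            missing.append(rid)
            continue
        fcc[rid] = (lnj[0] - lnj[1]) / d
    return MCAResult(cell=cell, flux_id=flux_id, base_flux=j0, fcc=fcc,
                     perturbation=rel_perturbation, missing=missing)


def average_stoichiometric_number(cell: CellModel,
                                  key_enzymes: Iterable[str],
                                  fcc: Mapping[str, float] | None = None,
                                  mode: str = "control") -> float:
    """Average stoichiometric number chi of a pathway.

    ``mode="sum"`` adds the occurrence numbers of the key (rate-limiting)
    enzymes; ``mode="control"`` (default) weights each occurrence number by
    the enzyme's flux control relative to the dominant one, which matches
    the convention that a step occurring twice but with somewhat weaker
    control contributes a little less than 2.
    """
    keys = list(key_enzymes)
    if not keys:
        raise ValueError("key_enzymes must not be empty")
    chis = {rid: cell.reaction(rid).chi_e for rid in keys}
    if mode == "sum" or fcc is None:
        return float(sum(chis.values()))
    if mode != "control":
        raise ValueError(f"unknown mode {mode!r}")
    top = max(fcc[rid] for rid in keys)
    if top <= 0:
        raise ValueError("key enzymes carry no flux control")
    return float(sum(chis[rid] * fcc[rid] / top for rid in keys))


def net_charge_translocation(cell: CellModel) -> float:
    """Net outward charges per substrate: sum of nu+ x chi_E over the
    membrane reactions, ATP synthase excluded."""
    return float(sum(
        r.nu_plus * r.chi_e for r in cell.reactions
        if r.kind == "membrane" and r.id != cell.atpase_id
    ))


def atp_yield(net_charge: float, ions_per_atp: float,
              atp_consumed: float = 0.0) -> float:
    """Mol ATP per mol substrate from the chemiosmotic charge balance.

    ``net_charge`` is the net outward translocation per substrate;
    ``atp_consumed`` the ATP spent on substrate activation (its charge cost
    is ions_per_atp per ATP).  Negative yields are allowed (an infeasible
    design) and should be flagged by the caller.
    """
    if ions_per_atp <= 0:
        raise ValueError("ions_per_atp must be positive")
    return (net_charge - ions_per_atp * atp_consumed) / ions_per_atp


def thermodynamic_efficiency(y_atp: float, delta_g_p: float,
                             delta_g_allocated: float) -> float:
    """Percent of the allocated catabolic energy conserved in ATP."""
    if delta_g_allocated == 0:
        raise ValueError("allocated energy must be non-zero")
    return 100.0 * y_atp * delta_g_p / abs(delta_g_allocated)


def roi(energy_conserved: float, energy_invested: float) -> float:
    """Return on investment, percent."""
    if energy_invested <= 0:
        raise ValueError("invested energy must be positive")
    return 100.0 * energy_conserved / energy_invested


def biomass_yield(y_atp: float, g_per_mol_atp: float = 5.0,
                  allocation: float = 0.5) -> float:
    """Cell dry weight per mol substrate from the ATP yield (g/mol)."""
    return y_atp * g_per_mol_atp * allocation


def drive_fcc_correlation(drives: Sequence[float], fccs: Sequence[float],
                          n_permutations: int = 10000,
                          seed: int = 0) -> tuple[float, float]:
    """Spearman rank correlation between drives and FCCs with a
    permutation p-value (average ranks for ties)."""
    drives = np.asarray(drives, dtype=float)
    fccs = np.asarray(fccs, dtype=float)
    if len(drives) < 3 or len(drives) != len(fccs):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(drives) == 0 or np.ptp(fccs) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rho = float(spearmanr(drives, fccs).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(fccs)
        if abs(float(spearmanr(drives, perm).statistic)) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return rho, p


# ---------------------------------------------------------------------------
# The bioenergetic ledger
# ---------------------------------------------------------------------------

@dataclass
class CellLedger:
    cell: str
    allocated: float          # kJ per mol substrate made available to the cell
    net_charge: float         # charges translocated out per substrate
    atp_consumed: float       # ATP invested in substrate activation
    y_atp: float              # mol ATP per mol substrate
    delta_g_p: float          # phosphorylation energy, kJ/mol
    eta: float                # % of allocated energy conserved as ATP
    roi_atp_equivalents: float
    roi_membrane_dissipation: float | None
    f: float                  # pathway thermodynamic drive, kJ/mol
    chi: float
    f_t: float
    delta_psi_mv: float
    drive_sum: float          # sum chi_E * f_i over the cell's reactions
    drive_residual: float     # f - drive_sum (diffusion/carrier steps etc.)


@dataclass
class BioenergeticLedger:
    cells: dict[str, CellLedger]
    delta_g_total: float
    eta_total: float
    y_atp_total: float
    enzyme_table: pd.DataFrame

    def self_consistent(self, tol: float = 0.1) -> bool:
        """eta recomputed from the stored fields matches the stored eta."""
        for led in self.cells.values():
            eta = thermodynamic_efficiency(led.y_atp, led.delta_g_p,
                                           led.allocated)
            if abs(eta - led.eta) > tol:
                return False
        return True


def _allocated_energies(model: ConsortiumModel, state) -> tuple[float, float, float]:
    """(to ANME, to SRB, total) in kJ per mol substrate, from the actual
    potentials of the donor couple, the shared carrier, and the acceptor."""
    from .aom_sr import STANDARD_POTENTIALS_MV as E0

    ctx = ThermoContext(temperature=model.temperature, ph=model.ph)
    rt, f = ctx.rt, ctx.F
    ox, red = model.diet_carrier
    e_tpic = E0["TpIc3"] - (rt / (1 * f)) * math.log(
        state.concentration(red) / state.concentration(ox)) * 1e3
    e_don = E0["CH4/HCO3"] - (rt / (8 * f)) * math.log(
        state.concentration("CH4@e") / state.concentration("HCO3@e")) * 1e3
    e_acc = E0["SO4/H2S"] - (rt / (8 * f)) * math.log(
        state.concentration("H2S@e") / state.concentration("SO4@e")) * 1e3
    to_anme = 8 * f * (e_tpic - e_don) * 1e-3
    to_srb = 8 * f * (e_acc - e_tpic) * 1e-3
    return to_anme, to_srb, to_anme + to_srb


def bioenergetic_report(model: ConsortiumModel, result: SteadyStateResult,
                        mca: Mapping[str, MCAResult] | None = None,
                        ) -> BioenergeticLedger:
    """Assemble the bioenergetic ledger from a converged steady state.

    ``mca`` (per-cell MCA results) refines the key-enzyme set and the
    control-weighted chi; without it, chi falls back to the occurrence-sum
    over the two largest drive consumers.
    """
    if not result.converged:
        raise RuntimeError("refusing to report on an unconverged state")
    ctx = ThermoContext(temperature=model.temperature, ph=model.ph)
    dgp = phosphorylation_energy(1e-2, 1e-3, 1e-2, ctx=ctx)
    alloc = {"ANME": None, "SRB": None}
    alloc["ANME"], alloc["SRB"], total = _allocated_energies(model, result.state)

    rows = []
    ledgers: dict[str, CellLedger] = {}
    for cname, cell in model.cells.items():
        j = result.pathway_flux(cname)
        net = net_charge_translocation(cell)
        consumed = _activation_atp(cell)
        y = atp_yield(net, cell.ions_per_atp, consumed)
        psi = result.state.delta_psi[cname]
        conserved = y * cell.ions_per_atp * F_KJ * psi
        f_drive = alloc[cname] - conserved
        # per-enzyme drives from the simulated state
        drive_sum = 0.0
        for rxn in cell.reactions:
            if rxn.id == cell.atpase_id:
                continue
            chi_eff = (result.fluxes[(cname, rxn.id)] / j) if j else rxn.chi_e
            drive_sum += -result.delta_g[(cname, rxn.id)] * chi_eff
        if mca and cname in mca:
            ranked = mca[cname].ranked()
            keys = [ranked[0][0], ranked[1][0]]
            chi = average_stoichiometric_number(cell, keys, mca[cname].fcc)
        else:
            drives = {
                r.id: -result.delta_g[(cname, r.id)] * r.chi_e
                for r in cell.reactions
                if r.id in cell.enzymes and r.id != cell.atpase_id
            }
            keys = sorted(drives, key=drives.get)[-2:]
            chi = sum(cell.reaction(k).chi_e for k in keys)
        f_t = thermodynamic_potential_factor(f_drive, chi, ctx) \
            if f_drive > 0 else 0.0
        inward = sum(
            -r.nu_plus * r.chi_e for r in cell.reactions
            if r.kind == "membrane" and r.id != cell.atpase_id and r.nu_plus < 0
        )
        invest_equiv = consumed + inward / cell.ions_per_atp if consumed \
            else inward / cell.ions_per_atp
        roi_equiv = roi(y * dgp, invest_equiv * dgp) if invest_equiv > 0 \
            else float("nan")
        roi_memb = roi(y * dgp, inward * F_KJ * psi) if inward > 0 \
            else None
        ledgers[cname] = CellLedger(
            cell=cname, allocated=alloc[cname], net_charge=net,
            atp_consumed=consumed, y_atp=y, delta_g_p=dgp,
            eta=thermodynamic_efficiency(y, dgp, alloc[cname]),
            roi_atp_equivalents=roi_equiv,
            roi_membrane_dissipation=roi_memb,
            f=f_drive, chi=chi, f_t=f_t, delta_psi_mv=psi * 1e3,
            drive_sum=drive_sum, drive_residual=f_drive - drive_sum,
        )
        for rxn in cell.reactions:
            if rxn.id not in cell.enzymes:
                continue
            enz = cell.enzymes[rxn.id]
            rows.append({
                "cell": cname, "enzyme": rxn.id,
                "delta_g_chemical_kj_mol": result.delta_g_chemical[(cname, rxn.id)],
                "phi_percent": enz.phi * 100.0,
                "nu_plus": rxn.nu_plus, "chi_e": rxn.chi_e,
                "f_kj_mol": -result.delta_g[(cname, rxn.id)],
                "fcc": (mca[cname].fcc.get(rxn.id, float("nan"))
                        if mca and cname in mca else float("nan")),
                "flux_mmol_g_d": result.fluxes[(cname, rxn.id)],
            })

    y_total = sum(l.y_atp for l in ledgers.values())
    return BioenergeticLedger(
        cells=ledgers,
        delta_g_total=total,
        eta_total=thermodynamic_efficiency(y_total, dgp, total),
        y_atp_total=y_total,
        enzyme_table=pd.DataFrame(rows),
    )


def _activation_atp(cell: CellModel) -> float:
    """Mol ATP hydrolysed per substrate in activation steps (from the
    pathway stoichiometry of reactions consuming ATP)."""
    total = 0.0
    for rid, chi in cell.pathway_chi.items():
        rxn = cell.reaction(rid)
        for sid, nu in rxn.equation.items():
            if sid.startswith("ATP") and nu < 0:
                total += -nu * chi
    return total
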