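"""Dynamic optimization of proteome allocation and ion translocation.

The dual objective — maximise each partner's ATP production flux over its
enzyme proteome fractions phi and ion-translocation stoichiometries nu+ —
is solved by control-vector parameterisation: a derivative-free outer
search (Nelder-Mead with seeded simplex jitter and restart-on-stall) over
the control vector, with an inner initial-value problem solved to steady
state for every candidate.  The consortium problem is decomposed by the
energy-partition fraction f_G: the shared electron-carrier potential is
clamped between the donor and acceptor couples, each cell is optimised
against that fixed interface, and the Pareto front is scanned for the
partition at which both partners achieve equal substrate uptake and ATP
production fluxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .kinetics import Simulator, SteadyStateResult
from .model_core import ConsortiumModel
from .thermo import ThermoContext

__all__ = [
    "ControlVector",
    "OptimizationResult",
    "maximize_atp_flux",
    "pareto_energy_partition",
    "couple_consortium",
    "set_diet_potential",
]

_FAIL = -1.0e6  # objective sentinel for infeasible candidates


@dataclass
class ControlVector:
    """Optimisable proteome fractions and ion-translocation numbers."""

    phi: dict[str, float]
    nu_plus: dict[str, float] = field(default_factory=dict)
    phi_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    nu_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for rid, v in self.phi.items():
            lo, hi = self.phi_bounds.get(rid, (0.0, 1.0))
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                raise ValueError(f"phi[{rid}] = {v} outside [{lo}, {hi}]")
        for rid, v in self.nu_plus.items():
            lo, hi = self.nu_bounds.get(rid, (-2.0, 2.0))
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ValueError(f"nu_plus[{rid}] = {v} outside [{lo}, {hi}]")


@dataclass
class OptimizationResult:
    cell: str
    control: ControlVector
    j_atp: float
    uptake: float
    steady_state: SteadyStateResult | None
    trace: list[float]
    n_eval: int
    f_g: float | None = None
    converged: bool = True


def set_diet_potential(model: ConsortiumModel, e_mv: float) -> None:
    """Clamp the shared electron-carrier pool at a reduction potential.

    The carrier total is preserved; only the red/ox ratio is set (Nernst,
    one electron)."""
    from .aom_sr import STANDARD_POTENTIALS_MV as E0

    ctx = ThermoContext(temperature=model.temperature, ph=model.ph)
    ox_id, red_id = model.diet_carrier
    ox = model.metabolites[ox_id]
    red = model.metabolites[red_id]
    total = ox.concentration + red.concentration
    ratio = math.exp((E0["TpIc3"] - e_mv) * 1e-3 * ctx.F / ctx.rt)  # red/ox
    ox.concentration = total / (1.0 + ratio)
    red.concentration = total - ox.concentration


def _apply_control(model: ConsortiumModel, cell: str, cv: ControlVector) -> None:
    from dataclasses import replace

    cobj = model.cells[cell]
    for rid, phi in cv.phi.items():
        cobj.enzymes[rid] = replace(cobj.enzymes[rid], phi=phi)
    for rid, nu in cv.nu_plus.items():
        cobj.reaction(rid).nu_plus = nu


def _project(x: np.ndarray, names: Sequence[tuple[str, str]],
             cv: ControlVector, cell) -> ControlVector:
    """Clip a raw parameter vector into bounds and pool caps."""
    phi = dict(cv.phi)
    nu = dict(cv.nu_plus)
    for val, (kind, rid) in zip(x, names):
        if kind == "phi":
            lo, hi = cv.phi_bounds.get(rid, (0.0, 1.0))
            phi[rid] = float(min(max(val, lo), hi))
        else:
            lo, hi = cv.nu_bounds.get(rid, (-2.0, 2.0))
            nu[rid] = float(min(max(val, lo), hi))
    # proteome pool caps: scale each pool down proportionally if exceeded
    for kind_name, cap in (("membrane", cell.membrane_pool_cap),
                           ("cytoplasmic", cell.cytoplasm_pool_cap)):
        pool = [rid for rid in phi
                if cell.reaction(rid).kind == kind_name]
        tot = sum(phi[rid] for rid in pool) + sum(
            e.phi for rid2, e in cell.enzymes.items()
            if cell.reaction(rid2).kind == kind_name and rid2 not in phi
        )
        if tot > cap:
            scale = cap / tot
            for rid in pool:
                phi[rid] *= scale
    return ControlVector(phi=phi, nu_plus=nu, phi_bounds=cv.phi_bounds,
                         nu_bounds=cv.nu_bounds)


def maximize_atp_flux(model: ConsortiumModel, cell: str,
                      optimize_phi: Iterable[str] | None = None,
                      optimize_nu: Iterable[str] | None = None,
                      seed: int = 0, maxiter: int = 400, restarts: int = 3,
                      uptake_target: float | None = None,
                      clamp_diet: bool = True,
                      x0_state: SteadyStateResult | None = None,
                      ) -> OptimizationResult:
    """Maximise a cell's steady-state ATP production flux.

    The partner interface (shared carrier) is clamped, the cell is solved
    alone, and Nelder-Mead searches the control vector.  Candidates whose
    inner problem fails to converge, or whose ATP flux is negative, receive
    a hard failure sentinel and are never returned.  ``uptake_target``
    re-solves the problem with the substrate uptake flux pinned (quadratic
    penalty), which is how the consortium coupling re-computes the stronger
    partner.
    """
    work = model.copy()
    cobj = work.cells[cell]
    if optimize_phi is None:
        optimize_phi = [rid for rid in cobj.enzymes]
    if optimize_nu is None:
        optimize_nu = []
    cv = ControlVector(
        phi={rid: cobj.enzymes[rid].phi for rid in optimize_phi},
        nu_plus={rid: cobj.reaction(rid).nu_plus for rid in optimize_nu},
        phi_bounds={rid: (0.0, cobj.enzymes[rid].phi_max)
                    for rid in optimize_phi},
        nu_bounds={rid: (-cobj.reaction(rid).nu_plus_max,
                         cobj.reaction(rid).nu_plus_max)
                   for rid in optimize_nu},
    )
    names = [("phi", rid) for rid in cv.phi] + [("nu", rid) for rid in cv.nu_plus]
    x0 = np.array([cv.phi[rid] for rid in cv.phi]
                  + [cv.nu_plus[rid] for rid in cv.nu_plus])

    clamp = work.diet_carrier if clamp_diet else ()
    base_state = (x0_state.state if x0_state is not None else None)
    cache: dict = {"state": base_state, "best": _FAIL, "best_cv": cv,
                   "best_res": None, "trace": [], "n": 0}

    def objective(x: np.ndarray) -> float:
        cache["n"] += 1
        trial = work.copy()
        cvx = _project(x, names, cv, trial.cells[cell])
        _apply_control(trial, cell, cvx)
        sim = Simulator(trial, active_cells=[cell], clamp_species=clamp)
        try:
            if cache["state"] is not None:
                res = sim.refine_from(cache["state"])
            else:
                res = sim.solve_steady_state()
        except Exception:
            return -_FAIL
        if not res.converged:
            return -_FAIL
        j = res.atp_flux(cell)
        if j < 0:
            return -_FAIL
        value = j
        if uptake_target is not None:
            value -= 1e5 * ((res.pathway_flux(cell) - uptake_target)
                            / max(abs(uptake_target), 1e-9)) ** 2
        if value > cache["best"]:
            cache.update(best=value, best_cv=cvx, best_res=res,
                         state=res.state)
        cache["trace"].append(cache["best"])
        return -value

    rng = np.random.default_rng(seed)
    x_start = x0.copy()
    for attempt in range(restarts):
        simplex = [x_start]
        for _ in range(len(x_start)):
            jitter = 1.0 + 0.1 * rng.uniform(-1.0, 1.0, size=x_start.shape)
            simplex.append(x_start * jitter + 1e-4 * rng.standard_normal(
                x_start.shape) * (x_start == 0))
        out = minimize(objective, x_start, method="Nelder-Mead",
                       options={"maxiter": maxiter, "fatol": 1e-6,
                                "xatol": 1e-8,
                                "initial_simplex": np.array(simplex)})
        x_start = out.x
        if out.success:
            break

    if cache["best_res"] is None:
        raise RuntimeError(
            f"no feasible control vector found for {cell} "
            f"({cache['n']} evaluations)")
    res = cache["best_res"]
    return OptimizationResult(
        cell=cell, control=cache["best_cv"], j_atp=res.atp_flux(cell),
        uptake=res.pathway_flux(cell), steady_state=res,
        trace=cache["trace"], n_eval=cache["n"],
    )


def pareto_energy_partition(model: ConsortiumModel,
                            f_g_grid: Sequence[float],
                            e_donor_mv: float | None = None,
                            e_acceptor_mv: float | None = None,
                            optimize: bool = False, seed: int = 0,
                            maxiter: int = 150) -> pd.DataFrame:
    """ATP production fluxes of both partners along the energy partition.

    For each fraction ``f_G`` of the total redox span allocated to the
    first cell, the shared carrier is clamped at the corresponding
    potential and both single-cell problems are solved (optionally
    re-optimised).  Returns a frame with columns ``f_g``, ``j_atp_<cell>``
    and ``uptake_<cell>``; the crossing of the two ATP-flux columns is the
    balanced partition.
    """
    if len(f_g_grid) == 0:
        raise ValueError("empty f_G grid")
    if any(not (0.0 <= f <= 1.0) for f in f_g_grid):
        raise ValueError("f_G values must lie in [0, 1]")
    if e_donor_mv is None or e_acceptor_mv is None:
        from .aom_sr import STANDARD_POTENTIALS_MV as E0
        e_donor_mv = E0["CH4/HCO3"] if e_donor_mv is None else e_donor_mv
        e_acceptor_mv = E0["SO4/H2S"] if e_acceptor_mv is None else e_acceptor_mv

    rows = []
    cells = list(model.cells)
    warm: dict[str, object] = {}
    for f_g in f_g_grid:
        work = model.copy()
        e_mv = e_donor_mv + f_g * (e_acceptor_mv - e_donor_mv)
        set_diet_potential(work, e_mv)
        row: dict[str, float] = {"f_g": f_g, "e_carrier_mv": e_mv}
        for cname in cells:
            if optimize:
                try:
                    opt = maximize_atp_flux(work, cname, seed=seed,
                                            maxiter=maxiter)
                    row[f"j_atp_{cname}"] = opt.j_atp
                    row[f"uptake_{cname}"] = opt.uptake
                except RuntimeError:
                    row[f"j_atp_{cname}"] = float("nan")
                    row[f"uptake_{cname}"] = float("nan")
            else:
                sim = Simulator(work, active_cells=[cname],
                                clamp_species=work.diet_carrier)
                try:
                    if cname in warm:
                        res = sim.refine_from(warm[cname])
                    else:
                        res = sim.solve_steady_state()
                except Exception:
                    res = None
                if res is not None and res.converged:
                    warm[cname] = res.state
                ok = res is not None and res.converged
                row[f"j_atp_{cname}"] = res.atp_flux(cname) if ok else float("nan")
                row[f"uptake_{cname}"] = res.pathway_flux(cname) if ok else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def crossing_point(front: pd.DataFrame, col_a: str, col_b: str,
                   x_col: str = "f_g") -> float:
    """Linear-interpolated crossing of two columns along the grid."""
    d = (front[col_a] - front[col_b]).to_numpy()
    x = front[x_col].to_numpy()
    for k in range(len(d) - 1):
        if d[k] == 0:
            return float(x[k])
        if d[k] * d[k + 1] < 0:
            w = d[k] / (d[k] - d[k + 1])
            return float(x[k] + w * (x[k + 1] - x[k]))
    raise ValueError("no crossing on the grid")


def couple_consortium(model: ConsortiumModel,
                      result_a: OptimizationResult,
                      result_b: OptimizationResult,
                      tol: float = 1e-3, seed: int = 0,
                      maxiter: int = 300) -> tuple[OptimizationResult,
                                                   OptimizationResult]:
    """Enforce the consortium coupling: equal substrate uptake (and hence
    equal electron and ATP-production balance) between the partners.

    The partner with the larger ATP production flux is re-optimised with
    its substrate uptake pinned to the other's; partners already matched
    are returned unchanged.
    """
    ja, jb = result_a.j_atp, result_b.j_atp
    if abs(ja - jb) <= tol * max(abs(ja), abs(jb), 1e-12):
        return result_a, result_b
    if ja > jb:
        strong, weak = result_a, result_b
    else:
        strong, weak = result_b, result_a
    work = model.copy()
    _apply_control(work, strong.cell, strong.control)
    redone = maximize_atp_flux(
        work, strong.cell, optimize_phi=list(strong.control.phi),
        optimize_nu=list(strong.control.nu_plus), seed=seed,
        maxiter=maxiter, uptake_target=weak.uptake,
        x0_state=strong.steady_state)
    pair = (redone, weak) if ja > jb else (weak, redone)
    return pair if result_a.cell == pair[0].cell else (pair[1], pair[0])
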