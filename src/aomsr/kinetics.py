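"""Rate laws with thermodynamic feedback and steady-state integration.

Each enzyme follows a reversible saturation law throttled by the
thermodynamic potential factor,

    v = kcat [E] * prod_s c_s/(Km_s + c_s) * (1 - exp(dG/(chi_E R T))),

so the rate vanishes exactly at equilibrium and runs backwards when dG > 0.
Diffusive exchange follows a linear gradient law; the extracellular
electron-carrier exchange uses the same thermodynamic factor with a fixed
capacity.  Membrane potentials obey

    d(dpsi)/dt = (F / C_m) * sum_i nu+_i v_i,

charging with net outward translocation.  Unclamped concentrations are
integrated in log space (positivity preserved) with a stiff solver and the
result is polished by damped least squares on the stationarity residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .model_core import ConsortiumModel, Reaction
from .thermo import ThermoContext, equilibrium_constant

__all__ = [
    "SystemState",
    "SteadyStateResult",
    "Simulator",
    "reaction_rate",
    "diffusion_flux",
    "membrane_potential_rate",
    "integrate_to_steady_state",
]

# Cap on the positive exponent of the thermodynamic factor: limits how fast a
# strongly disfavoured reaction may run backwards (|factor| <= e^6 - 1).
_REVERSE_EXP_CAP = 6.0


@dataclass
class SystemState:
    """Concentrations (mol/kg), membrane potentials (V) and time (d)."""

    concentrations: dict[str, float]
    delta_psi: dict[str, float] = field(default_factory=dict)
    time: float = 0.0

    def concentration(self, sid: str) -> float:
        return self.concentrations[sid]

    def copy(self) -> "SystemState":
        return SystemState(dict(self.concentrations), dict(self.delta_psi),
                           self.time)


@dataclass
class SteadyStateResult:
    """Converged state with per-reaction fluxes and free energies.

    Fluxes in mmol per g dry weight per day; ``delta_g`` is the full
    chemiosmotic value and ``delta_g_chemical`` the RT ln(Q/K) part.
    ``residual`` is the largest stationarity defect (relative concentration
    derivative per day, or charge-flux imbalance in mmol g-1 d-1).
    """

    state: SystemState
    fluxes: dict[tuple[str, str], float]
    delta_g: dict[tuple[str, str], float]
    delta_g_chemical: dict[tuple[str, str], float]
    converged: bool
    residual: float
    diagnostics: dict = field(default_factory=dict)
    uptake_reactions: dict[str, str] = field(default_factory=dict)

    def flux(self, cell: str, rid: str) -> float:
        return self.fluxes[(cell, rid)]

    def atp_flux(self, cell: str) -> float:
        return self.fluxes[(cell, "ATPase")]

    def pathway_flux(self, cell: str) -> float:
        """Substrate uptake flux of a cell (methane or sulphate)."""
        key = self.uptake_reactions.get(
            cell, "D_CH4" if (cell, "D_CH4") in self.fluxes else "SULP")
        return self.fluxes[(cell, key)]


def _chi_for_rate(rxn: Reaction, is_atpase: bool = False) -> float:
    # The ATP synthase's occurrence number is pathway bookkeeping (ATP made
    # per substrate), not an internal rate-limiting stoichiometry, so its
    # rate law uses chi = 1; other occurrence numbers below 1 floor at 1.
    if is_atpase or rxn.chi_e < 1.0:
        return 1.0
    return rxn.chi_e


def _thermo_factor(dg: float, chi: float, rt: float) -> float:
    x = dg / (chi * rt)
    if x > _REVERSE_EXP_CAP:
        x = _REVERSE_EXP_CAP
    return -math.expm1(x)


def reaction_rate(enzyme, reaction: Reaction, state: SystemState,
                  delta_psi: float, ctx: ThermoContext | None = None,
                  protein_per_gdw: float = 0.55) -> float:
    """Rate of one enzyme-catalysed reaction, mmol g^-1 d^-1.

    Sign follows the free energy: negative dG drives forward flux, dG = 0
    gives exactly zero, positive dG reverses the reaction (bounded).
    """
    ctx = ctx or ThermoContext()
    if enzyme.phi <= 0.0:
        return 0.0
    from .thermo import delta_g as _delta_g

    dg = _delta_g(reaction, state, delta_psi, ctx)
    is_atpase = reaction.id == "ATPase"
    sat = 1.0
    for sid, km in enzyme.km_map.items():
        c = state.concentration(sid)
        sat *= c / (km + c)
    vmax = enzyme.vmax(protein_per_gdw)
    return vmax * sat * _thermo_factor(dg, _chi_for_rate(reaction, is_atpase), ctx.rt)


def diffusion_flux(reaction: Reaction, state: SystemState) -> float:
    """Linear gradient exchange, mmol g^-1 d^-1 (antisymmetric in the
    gradient; zero when inner and outer concentrations agree)."""
    src = next(s for s, nu in reaction.equation.items() if nu < 0)
    dst = next(s for s, nu in reaction.equation.items() if nu > 0)
    k = reaction.rate_constant or 0.0
    return k * (state.concentration(src) - state.concentration(dst))


def membrane_potential_rate(fluxes: Mapping[str, float],
                            reactions: Sequence[Reaction],
                            c_m: float) -> float:
    """d(dpsi)/dt in V per day from per-reaction fluxes (mmol g^-1 d^-1)."""
    if c_m <= 0:
        raise ValueError("membrane capacitance must be positive")
    total = sum(r.nu_plus * fluxes.get(r.id, 0.0) for r in reactions)
    return 96485.0 * 1e-3 * total / c_m


class Simulator:
    """Assembles and solves the coupled ODE system of a consortium model.

    Parameters
    ----------
    model : ConsortiumModel
    active_cells : iterable of str, optional
        Restrict the dynamics to a subset of cells (the partner's reactions
        are switched off) — used for the decomposed single-cell problems.
    clamp_species : iterable of str, optional
        Additional species held constant (e.g. the shared electron-carrier
        pool when a cell is simulated against a fixed partner interface).
    """

    def __init__(self, model: ConsortiumModel,
                 active_cells: Iterable[str] | None = None,
                 clamp_species: Iterable[str] = (),
                 freeze_psi: bool = False) -> None:
        self.model = model
        self.freeze_psi = freeze_psi
        self.ctx = ThermoContext(temperature=model.temperature, ph=model.ph)
        self.cell_names = list(model.cells) if active_cells is None \
            else [c for c in model.cells if c in set(active_cells)]
        clamp = set(clamp_species)
        self.dynamic_ids = [
            sid for sid, met in model.metabolites.items()
            if not met.clamped and sid not in clamp and sid != "H2O"
        ]
        self._index = {sid: i for i, sid in enumerate(self.dynamic_ids)}
        self.n_dyn = len(self.dynamic_ids)
        self._conv = 1e-3 / model.cell_water  # mmol/g/d -> mol/kg/d
        self._reactions = [
            (cname, rxn) for cname in self.cell_names
            for rxn in model.cells[cname].reactions
        ]
        # Pre-compute equilibrium constants (fixed given dG0' and pH-7 ref).
        self._ln_k = {
            (c, r.id): math.log(equilibrium_constant(r, self.ctx))
            for c, r in self._reactions
        }
        self.uptake_reactions: dict[str, str] = {}
        for cname in self.cell_names:
            cell = model.cells[cname]
            for rxn in cell.reactions:
                if cell.substrate_id and rxn.equation.get(cell.substrate_id, 0) < 0:
                    self.uptake_reactions[cname] = rxn.id
                    break
        # Conserved-moiety matrix: left null space of the dynamic
        # stoichiometric matrix.  Pool totals are invariants of the
        # dynamics; the polish step anchors them so refinement cannot
        # wander along the conserved manifold.
        if self.n_dyn:
            s_mat = np.zeros((self.n_dyn, len(self._reactions)))
            for k, (cname, rxn) in enumerate(self._reactions):
                for sid, nu in rxn.equation.items():
                    i = self._index.get(sid)
                    if i is not None:
                        s_mat[i, k] = nu
            from scipy.linalg import null_space
            self._conservation = null_space(s_mat.T).T  # (k, n_dyn)
        else:
            self._conservation = np.zeros((0, 0))

    # -- state packing ------------------------------------------------------

    def initial_state(self) -> SystemState:
        conc = {sid: m.concentration for sid, m in self.model.metabolites.items()}
        psi = {c: self.model.cells[c].membrane_potential for c in self.cell_names}
        return SystemState(conc, psi, 0.0)

    @property
    def n_psi(self) -> int:
        return 0 if self.freeze_psi else len(self.cell_names)

    def pack(self, state: SystemState) -> np.ndarray:
        y = np.empty(self.n_dyn + self.n_psi)
        for sid, i in self._index.items():
            y[i] = math.log(state.concentrations[sid])
        if self.freeze_psi:
            self._fixed_psi = dict(state.delta_psi)
        else:
            for j, cname in enumerate(self.cell_names):
                y[self.n_dyn + j] = state.delta_psi[cname]
        return y

    def unpack(self, y: np.ndarray, t: float = 0.0) -> SystemState:
        conc = {sid: m.concentration for sid, m in self.model.metabolites.items()}
        for sid, i in self._index.items():
            # clip to a physically meaningless but finite range so that a
            # diverging trajectory reports non-convergence instead of
            # overflowing
            conc[sid] = math.exp(min(max(y[i], -230.0), 23.0))
        if self.freeze_psi:
            psi = dict(getattr(self, "_fixed_psi", {
                c: self.model.cells[c].membrane_potential
                for c in self.cell_names}))
        else:
            psi = {c: y[self.n_dyn + j] for j, c in enumerate(self.cell_names)}
        return SystemState(conc, psi, t)

    # -- rates --------------------------------------------------------------

    def reaction_fluxes(self, state: SystemState) -> dict[tuple[str, str], float]:
        model, ctx = self.model, self.ctx
        rt = ctx.rt
        out: dict[tuple[str, str], float] = {}
        for cname, rxn in self._reactions:
            cell = model.cells[cname]
            if rxn.kind == "diffusion":
                out[(cname, rxn.id)] = diffusion_flux(rxn, state)
                continue
            # ln Q with clamped protons and unit water activity
            ln_q = 0.0
            ok = True
            for sid, nu in rxn.equation.items():
                if sid == "H2O":
                    continue
                c = state.concentrations[sid]
                if c <= 0.0:
                    ok = False
                    break
                ln_q += nu * math.log(c)
            if not ok:
                out[(cname, rxn.id)] = 0.0
                continue
            dg = rt * (ln_q - self._ln_k[(cname, rxn.id)]) \
                + rxn.nu_plus * ctx.F * state.delta_psi[cname]
            factor = _thermo_factor(
                dg, _chi_for_rate(rxn, rxn.id == cell.atpase_id), rt)
            enz = cell.enzymes.get(rxn.id)
            if enz is not None:
                if enz.phi <= 0.0:
                    out[(cname, rxn.id)] = 0.0
                    continue
                sat = 1.0
                for sid, km in enz.km_map.items():
                    c = state.concentrations[sid]
                    sat *= c / (km + c)
                cap = enz.vmax(cell.protein_per_gdw) * sat
            else:
                cap = rxn.rate_constant or 0.0
            out[(cname, rxn.id)] = cap * factor
        return out

    def delta_g_map(self, state: SystemState, chemical: bool = False
                    ) -> dict[tuple[str, str], float]:
        rt = self.ctx.rt
        out: dict[tuple[str, str], float] = {}
        for cname, rxn in self._reactions:
            if rxn.kind == "diffusion":
                src = next(s for s, nu in rxn.equation.items() if nu < 0)
                dst = next(s for s, nu in rxn.equation.items() if nu > 0)
                out[(cname, rxn.id)] = rt * math.log(
                    state.concentrations[dst] / state.concentrations[src])
                continue
            ln_q = sum(
                nu * math.log(state.concentrations[sid])
                for sid, nu in rxn.equation.items() if sid != "H2O"
            )
            dg = rt * (ln_q - self._ln_k[(cname, rxn.id)])
            if not chemical:
                dg += rxn.nu_plus * self.ctx.F * state.delta_psi[cname]
            out[(cname, rxn.id)] = dg
        return out

    def _residuals(self, y: np.ndarray) -> np.ndarray:
        """Stationarity residuals: d ln c/dt (1/d) and charge flux (mmol/g/d)."""
        state = self.unpack(y)
        fluxes = self.reaction_fluxes(state)
        dcdt = np.zeros(self.n_dyn)
        for (cname, rid), v in fluxes.items():
            rxn = self.model.cells[cname].reaction(rid)
            for sid, nu in rxn.equation.items():
                i = self._index.get(sid)
                if i is not None:
                    dcdt[i] += nu * v * self._conv
        res = np.empty(self.n_dyn + self.n_psi)
        for sid, i in self._index.items():
            res[i] = dcdt[i] / state.concentrations[sid]
        for j in range(self.n_psi):
            cname = self.cell_names[j]
            charge = sum(
                rxn.nu_plus * fluxes[(cname, rxn.id)]
                for rxn in self.model.cells[cname].reactions
            )
            res[self.n_dyn + j] = charge
        return res

    def _balance_residuals(self, y: np.ndarray) -> np.ndarray:
        """Flux-normalised stationarity residuals.

        Each species row is its net production divided by its throughput
        (sum of |nu x v| over reactions touching it, floored at
        1e-3 mmol g^-1 d^-1); each membrane-potential row is the charge-flux
        imbalance normalised the same way.  This is the steady-state metric
        used for convergence: it is scale-free in the pool sizes, so
        nanomolar intermediates are not judged by their absolute drift.
        """
        state = self.unpack(y)
        fluxes = self.reaction_fluxes(state)
        floor = 1e-3
        net = np.zeros(self.n_dyn)
        thru = np.full(self.n_dyn, floor)
        for (cname, rid), v in fluxes.items():
            rxn = self.model.cells[cname].reaction(rid)
            for sid, nu in rxn.equation.items():
                i = self._index.get(sid)
                if i is not None:
                    net[i] += nu * v
                    thru[i] += abs(nu * v)
        res = np.empty(self.n_dyn + self.n_psi)
        res[: self.n_dyn] = net / thru
        for j in range(self.n_psi):
            cname = self.cell_names[j]
            charge = pump = 0.0
            for rxn in self.model.cells[cname].reactions:
                v = fluxes[(cname, rxn.id)]
                charge += rxn.nu_plus * v
                pump += abs(rxn.nu_plus * v)
            res[self.n_dyn + j] = charge / (pump + floor)
        return res

    def rhs(self, t: float, y: np.ndarray, freeze_psi: bool = False
            ) -> np.ndarray:
        res = self._residuals(y)
        out = res.copy()
        for j in range(self.n_psi):
            cname = self.cell_names[j]
            if freeze_psi:
                out[self.n_dyn + j] = 0.0
            else:
                c_m = self.model.cells[cname].membrane_capacitance
                out[self.n_dyn + j] = 96485.0 * 1e-3 * res[self.n_dyn + j] / c_m
        return out

    # -- steady state -------------------------------------------------------

    def solve_steady_state(self, x0: SystemState | None = None,
                           horizon: float = 1e4, tol: float = 1e-8,
                           rtol: float = 1e-8, atol: float = 1e-10,
                           polish: bool = True) -> SteadyStateResult:
        state = (x0 or self.initial_state()).copy()
        y = self.pack(state)
        diagnostics: dict = {}

        def march(y, freeze_psi: bool, budget: float, key: str) -> np.ndarray:
            # Expanding-window stiff integration with early exit.
            t, window = 0.0, 1.0
            while t < budget:
                t_end = min(t + window, budget)
                sol = solve_ivp(lambda t_, y_: self.rhs(t_, y_, freeze_psi),
                                (t, t_end), y, method="BDF",
                                rtol=rtol, atol=atol)
                if not sol.success:
                    diagnostics[f"{key}_message"] = sol.message
                    break
                y = sol.y[:, -1]
                t = t_end
                window *= 4.0
                res = self._balance_residuals(y)
                if freeze_psi:
                    res = res[: self.n_dyn]
                if np.max(np.abs(res)) < max(tol, 1e-12) * 10:
                    break
            diagnostics[f"{key}_t"] = t
            return y

        # Phase 1: hold the membrane potentials at their configured values
        # while the metabolite pools relax to the chemiosmotic load (the
        # potentials relax orders of magnitude faster than the pools, so a
        # free start can fall into a transient-starved basin).  Phase 2:
        # release the potentials and integrate the full system.
        y0 = y.copy()
        if self.n_dyn and self.n_psi:
            y = march(y, True, horizon / 10.0, "phase1")
        y = march(y, False, horizon, "phase2")
        if polish:
            y = self.polish(y, anchor=y0)
        res = self._balance_residuals(y)
        residual = float(np.max(np.abs(res)))
        state = self.unpack(y, diagnostics.get("phase2_t", 0.0))
        fluxes = self.reaction_fluxes(state)
        return SteadyStateResult(
            state=state,
            fluxes=fluxes,
            delta_g=self.delta_g_map(state),
            delta_g_chemical=self.delta_g_map(state, chemical=True),
            converged=residual < tol,
            residual=residual,
            diagnostics=diagnostics,
            uptake_reactions=dict(self.uptake_reactions),
        )

    def _conserved_totals(self, y: np.ndarray) -> np.ndarray:
        if not len(self._conservation):
            return np.zeros(0)
        c = np.exp(y[: self.n_dyn])
        return self._conservation @ c

    def polish(self, y: np.ndarray,
               anchor: np.ndarray | None = None) -> np.ndarray:
        """Damped least-squares refinement of the balance residuals.

        ``anchor`` (a packed state) supplies the conserved pool totals the
        refined solution must keep; defaults to ``y`` itself.
        """
        totals0 = self._conserved_totals(anchor if anchor is not None else y)
        scale = np.abs(self._conservation) @ np.exp(
            (anchor if anchor is not None else y)[: self.n_dyn]) \
            if len(self._conservation) else np.zeros(0)
        scale = np.where(scale > 0, scale, 1.0)

        def fun(z):
            base = self._balance_residuals(z)
            if not len(self._conservation):
                return base
            defect = (self._conserved_totals(z) - totals0) / scale
            return np.concatenate([base, defect])

        best = y
        best_res = np.max(np.abs(fun(y)))
        for method in ("trf", "lm"):
            try:
                sol = least_squares(fun, best, method=method, xtol=1e-15,
                                    ftol=1e-15, gtol=1e-15, max_nfev=20000)
            except Exception:  # pragma: no cover - refinement is best-effort
                continue
            if np.all(np.isfinite(sol.x)):
                r = np.max(np.abs(fun(sol.x)))
                if r < best_res:
                    best, best_res = sol.x, r
        return best

    def refine_from(self, base: SystemState, tol: float = 1e-8
                    ) -> SteadyStateResult:
        """Re-solve the steady state warm-started from a nearby solution."""
        y0 = self.pack(base)
        y = self.polish(y0, anchor=y0)
        res = self._balance_residuals(y)
        residual = float(np.max(np.abs(res)))
        if residual > tol:  # fall back to integration if the basin moved
            return self.solve_steady_state(self.unpack(y), tol=tol)
        state = self.unpack(y)
        return SteadyStateResult(
            state=state,
            fluxes=self.reaction_fluxes(state),
            delta_g=self.delta_g_map(state),
            delta_g_chemical=self.delta_g_map(state, chemical=True),
            converged=True,
            residual=residual,
            uptake_reactions=dict(self.uptake_reactions),
        )

    def time_course(self, t_eval: Sequence[float],
                    x0: SystemState | None = None,
                    rtol: float = 1e-8, atol: float = 1e-10):
        """Integrate and report states at the requested times (days)."""
        state = (x0 or self.initial_state()).copy()
        y0 = self.pack(state)
        sol = solve_ivp(self.rhs, (0.0, float(t_eval[-1])), y0, method="BDF",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        return [self.unpack(sol.y[:, k], sol.t[k]) for k in range(sol.y.shape[1])]


def integrate_to_steady_state(model: ConsortiumModel,
                              x0: SystemState | None = None,
                              horizon: float = 1e4, tol: float = 1e-8,
                              active_cells: Iterable[str] | None = None,
                              clamp_species: Iterable[str] = (),
                              ) -> SteadyStateResult:
    """Solve the consortium model to steady state (stiff IVP + polish)."""
    sim = Simulator(model, active_cells=active_cells,
                    clamp_species=clamp_species)
    return sim.solve_steady_state(x0=x0, horizon=horizon, tol=tol)
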