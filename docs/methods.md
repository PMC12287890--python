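# Methods

## Model structure

The consortium is three compartments: an environment with clamped
methane, bicarbonate, sulphate, sulphide and pH; an archaeal cell running
reverse methanogenesis; and a bacterial cell running dissimilatory
sulphate reduction.  Each cell is split conceptually into cytoplasmic and
membrane reactions; membrane reactions may translocate `ν+` ions per
event (outward positive).  The two cells share an extracellular
cytochrome pool (ox/red) through which all eight electrons per substrate
pass: the archaeon reduces it at its outer surface from the
methanophenazine pool, the bacterium oxidises it into its menaquinone
pool.  Cytoplasmic ATP (10 mM), ADP (1 mM) and phosphate (10 mM) are
clamped, giving a phosphorylation energy of 48.9 kJ/mol; water activity
is 1.

Reduced membrane electron carriers (MPH2, MQH2, TpIc_red) are tracked as
electron-only species (formal negative charge, no protons): the protons
they would carry enter the clamped pH pool.  This convention makes the
stoichiometric matrix times the occurrence-number vector reproduce the
lumped catabolic equations exactly — per methane,
`CH4(e) + 3 H2O + 4 MP → 9 H+ + HCO3−(e) + 4 MPH2`, and per sulphate
(after projecting the clamped phosphoryl pool out through the synthase
stoichiometry),
`SO4²−(e) + 10 H+ + 8 TpIc_red → H2S(e) + 4 H2O + 8 TpIc_ox`.

Network auditing balances each reaction up to implicit water and protons
(both clamped): all elements except H and O must balance exactly, O up to
added water, and the parity invariant `charge − n_H + 2 n_O` must be
conserved.  Removing a single hydrogen from any equation breaks the
parity and is flagged.

## Thermodynamics

Standard free energies are pH-7 transformed values.  Redox steps are
derived from standard couple potentials (methanophenazine −165 mV, F420
−360 mV, ferredoxin −500 mV, heterodisulfide −143 mV, extracellular
cytochrome −236 mV, menaquinone −74 mV, APS/AMP+sulphite −60 mV;
CH4/HCO3− −259.6 mV and SO4²−/H2S −217 mV for the lumped couples, the
latter chosen so the acceptor potential is −209.6 mV at 10 mM sulphate /
1 mM sulphide).  Two steps (formyl oxidation, sulphite reduction) are
fixed by Hess closure so that each pathway's standard-energy sum equals
its lumped redox energy exactly; methane activation is +17 kJ/mol and
methyl transfer +39.4 kJ/mol as written.  Quotients carry H+ explicitly
at `10^−pH`; the equilibrium constant of each written equation is shifted
by `(10⁻⁷)^{ΔnH+}` so the two conventions agree identically.

The thermodynamic potential factor is `F_T = 1 − exp(−f/(χRT))` with the
drive `f ≡ −ΔG` positive for a favourable step; only this sign yields
values in (0, 1) and reproduces the working-point value 0.51 from
f = 4.3 kJ/mol, χ = 2.46.

## Kinetics and parameter provenance

Rates are `v = kcat [E] · Π_s c_s/(Km_s + c_s) · (1 − exp(ΔG/(χ_E RT)))`,
with `[E] = φ · 0.55 g protein/g dw / molar mass`.  The sign of `v`
follows the free energy; the reverse-direction factor is capped at
`e⁶ − 1` so a strongly disfavoured step cannot run backwards unboundedly
fast.  The ATP synthase's occurrence number (ATP per substrate) is
pathway bookkeeping, not an internal stoichiometric number, so its rate
law uses χ = 1.

Per-enzyme kinetic constants for these uncultivated organisms are not
individually measurable.  The defaults are therefore *capacity*
calibrations: `V_i = χ_E,i · J* / F_T(f_i*)` with J* = 20 mmol g⁻¹ d⁻¹
and `f_i*` the reference per-enzyme drive column, so that the calibrated
network reproduces the reference working point (fluxes near
20 mmol g⁻¹ d⁻¹, drives concentrated on the methane-activating and
F420-oxidising steps in the archaeon and on APS reductase and
pyrophosphatase in the bacterium).  Michaelis constants default to 1/20
of each substrate's reference steady-state concentration, placing all
enzymes near saturation so that control is carried by the
thermodynamics; the reference concentrations themselves are the
self-consistent steady state of the capacity-calibrated network and ship
as the initial condition.  Proteome fractions and ion-translocation
numbers default to the reference optimum (methane-activating enzyme at
its 12% ceiling); membrane and cytoplasmic pool caps default to 20% and
40% — assumption flags, configurable.

Exchange steps (CH4, HCO3−, H2S, and the DIET electron transfer) use
effective mass-transfer capacities chosen large enough that exchange
dissipates ≪ 1 kJ/mol: at 4 μm aggregate diameter neither aqueous
diffusion nor carrier exchange is limiting, and the methane:sulphate
uptake-capacity ratio is 1.  The sodium/proton antiporter is included as
an electroneutral 1:1 exchanger between clamped pools (its coupling role
is implied but unspecified; with both ion pools clamped it carries no net
flux).

## Steady-state solution

Unclamped concentrations are integrated in log space (positivity
preserved) with BDF over expanding windows.  Because the membrane
potential relaxes orders of magnitude faster than the metabolite pools, a
free start can fall into a transiently starved low-flux basin; the solver
therefore first relaxes the metabolites with the membrane potentials held
at their configured values, then releases them.  The endpoint is refined
by damped least squares on *flux-normalised* balance residuals (net
production over throughput per species, charge imbalance over pumping per
membrane), with the conserved cofactor-pool totals anchored to the
initial state so refinement cannot wander along the conserved manifold.
Convergence means a maximum normalised residual below 1e−8; typical
converged residuals are 1e−12.  Divergent trajectories are clipped to a
finite concentration range and reported as non-converged, never silently
accepted.

## Control analysis

FCCs are central differences of ln J with respect to ln φ (±1% default),
with a full steady-state re-solve per perturbation, warm-started from the
base state.  Control is analysed per submodel: the shared carrier pool is
clamped and the membrane potential held at its steady-state value, so
each pathway is judged against its fixed energy budget; with the
adenylate pool clamped, the ATP synthase is at steady state and is
excluded.  Under this convention the summation theorem holds to ~1%
(exchange steps hold the residual), the two dominant controllers are the
methane-activating enzyme and the F420 oxidoreductase (archaeon) and APS
reductase and pyrophosphatase (bacterium), and simulated drives and FCCs
rank-correlate at ρ ≈ 1.00 / 0.96.

The average stoichiometric number χ of a pathway is reported two ways:
the plain occurrence sum of the key enzymes, and a control-weighted sum
(each occurrence number weighted by its FCC relative to the dominant one)
— the convention under which a step occurring twice with somewhat weaker
control contributes slightly less than 2.

## Bioenergetic ledger

Energy allocation is computed from actual potentials: donor couple (from
environmental CH4/HCO3−), acceptor couple (from SO4²−/H2S), and the
shared carrier's Nernst potential.  Net charge per substrate is
`Σ ν+ χ_E` over membrane reactions excluding the synthase; ATP yield is
`(net charge − ions/ATP × ATP invested)/ions per ATP` (3 H+/ATP for the
archaeon at ~200 mV, 4 for the bacterium at ~130 mV); efficiency is
`η = Y_ATP ΔG_p / allocated`.  ROI is implemented as two named
strategies: `atp_equivalents` (investment = activation ATP plus imported
activation charges converted at ions-per-ATP, times ΔG_p) and
`membrane_dissipation` (investment = imported charges × FΔψ).  The
ATP-equivalent strategy reproduces both published values (18% for the
archaeon from 4 imported charges / 3 H+ per ATP; 11% for the bacterium
from ~2.2 ATP equivalents); both are reported.  The ledger also reports
the per-cell drive bookkeeping `Σ χ f_i` and its residual against the
pathway drive — for the sulphate reducer a residual of ~1.9 kJ/mol sits
in the synthase dissipation and exchange steps and is surfaced rather
than hidden.

## Optimization

Control-vector parameterisation: Nelder–Mead (seeded ±10% simplex
jitter, up to three restarts) over proteome fractions and translocation
numbers, candidates clipped into bounds and proteome pools projected onto
their caps; the inner problem is the single-cell steady state against a
clamped carrier interface, with a hard failure sentinel for non-converged
or ATP-hydrolysing candidates.  The energy partition `f_G` maps to a
clamped carrier potential between donor and acceptor couples; the Pareto
scan solves both cells along an `f_G` grid, and the equal-uptake crossing
of the default network falls at a carrier potential of −236 mV,
allocating 18.2 and 20.4 kJ/mol to the two partners.  Consortium coupling
re-optimises the stronger partner with its substrate uptake pinned
(quadratic penalty) to the weaker partner's.

The seed governs only simplex jitter (and permutation p-values in the
correlation test); the inner dynamics are deterministic, so equal seeds
reproduce runs bit-identically.

## What the built-in network does and does not show

The network's boundary conditions, stoichiometry, translocation numbers,
proteome fractions, standard energies and the published working point are
inputs; the simulator then *reproduces* membrane potentials near 200/130
mV, equal uptake fluxes near 20 mmol g⁻¹ d⁻¹, the 26-fold sulphate
accumulation, drive partitioning, FCC structure, the ion-per-electron
law `ν+/n ≈ min(1, ΔE/Δψ)`, and the qualitative reversal (ATP-driven
methane production) when either inward-translocation step of methane
activation is removed.  Because the kinetic capacities are calibrated
rather than measured, absolute fluxes and intracellular concentrations
are working-point reconstructions, not predictions for any particular
enrichment culture; the exact published FCC values (reported
inconsistently as 0.51/0.33 in text and 0.44/0.36 in tabular form) are
treated as ordering information only.

## Known limitations

Single lumped gradient per species (no spatially resolved
reaction–diffusion inside the aggregate); no biomass-growth dynamics
(ATP-to-biomass is a static conversion at 5 g/mol ATP and 50%
allocation); no activity-coefficient or ionic-strength corrections; no
carbonate-speciation solver (equations are written directly in
bicarbonate); alternative electron acceptors and sulphur intermediates
are out of scope.  The low-flux steady state that exists alongside the
working point (reachable from strongly perturbed initial conditions) is
a genuine feature of thermodynamically coupled networks; the two-phase
solver documents and avoids it rather than removing it.
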