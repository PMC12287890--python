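# aomsr — bioenergetics of methane-oxidising consortia

`aomsr` is a thermodynamically constrained kinetic modelling framework for
two-member syntrophic consortia, built around the partnership that removes
most of the methane produced in marine sediments: anaerobic methanotrophic
archaea (ANME) oxidising methane by reverse methanogenesis, coupled through
direct interspecies electron transfer (DIET, via an extracellular
tetrahaem cytochrome c3 pool) to sulphate-reducing bacteria (SRB) running
the dissimilatory sulphate-reduction pathway.  The overall reaction

    CH4 + SO4^2- + H+  ->  HCO3- + H2S + H2O

releases only a few tens of kJ per mole, so the interesting questions are
quantitative: how is methane activated against a +17 kJ/mol barrier, how
many ions cross each membrane per substrate, what ATP yield and
thermodynamic efficiency result, and how strongly does the residual
thermodynamic drive limit the reaction rate?

## The model

Every enzyme reaction `i` carries a chemiosmotic free-energy change

    ΔG_i = RT ln(Q_i/K_i) + ν+_i F Δψ,

where `ν+_i` is the number of protons or sodium ions translocated outward
per reaction event and `Δψ` the membrane potential, which itself obeys

    dΔψ/dt = (F/C_m) Σ_i ν+_i v_i.

Rates follow reversible saturation kinetics throttled by the thermodynamic
potential factor `F_T = 1 − exp(ΔG/(χ_E RT))`, so every flux vanishes at
equilibrium and reverses beyond it.  The coupled stiff ODE system
(metabolites in both cytoplasms, the shared electron-carrier pool, and two
membrane potentials) is integrated to steady state and refined by damped
least squares.  On top of the simulator sit:

* **metabolic control analysis** — flux control coefficients
  `FCC_i = ∂ln J / ∂ln φ_i` by finite differences with a steady-state
  re-solve per perturbation (`aomsr.analysis`);
* **dynamic optimization** — Nelder–Mead search over enzyme proteome
  fractions `φ` and ion-translocation numbers `ν+` maximising ATP
  production flux, with an inner initial-value problem per candidate, and
  a Pareto scan over the fraction `f_G` of the redox span allocated to the
  methane oxidiser (`aomsr.optimize`);
* **a bioenergetic ledger** — net charge translocation, ATP yield
  `Y_ATP`, thermodynamic efficiency `η`, return on investment (ROI),
  pathway drive `f`, average stoichiometric number `χ` and `F_T`
  (`aomsr.analysis.bioenergetic_report`).

The built-in network (`aomsr.build_aomsr_model`) encodes the 12-step ANME
pathway (MCR, MTR, MER, MTD, MCH, FTR, FMD, HDR, FPO, RNF, MRP, ATP
synthase), the 8-step SRB pathway (SULP, SAT, PPA, APR, DSR, QRC, ADK, ATP
synthase), membrane exchange of CH4/HCO3−/H2S and the DIET couple, under
bioreactor boundary conditions (pH 7, 10 mM CH4, 10 mM HCO3−, 10 mM
SO4²−, 1 mM H2S, 25 °C).

## Worked example

```python
from aomsr import build_aomsr_model, integrate_to_steady_state
from aomsr.analysis import flux_control_coefficients, bioenergetic_report

model = build_aomsr_model()
state = integrate_to_steady_state(model)
mca = {c: flux_control_coefficients(model, c, base=state)
       for c in model.cells}
ledger = bioenergetic_report(model, state, mca)
```

or, from the shell, `aomsr report`, which prints:

```
| cell | allocated kJ/mol | net charge | Y_ATP | eta % | ROI % (ATP-equiv) | f kJ/mol | chi | F_T | delta_psi mV |
|---|---|---|---|---|---|---|---|---|---|
| ANME | 18.0 | 0.70 | 0.233 | 63.5 | 18 | 4.3 | 2.93 | 0.45 | 202.5 |
| SRB  | 20.6 | 8.93 | 0.232 | 55.2 | 11 | 9.0 | 1.89 | 0.85 | 129.2 |
```

Reading the rows: of the ~38.6 kJ/mol released per methane, the carrier
pool settles at a reduction potential (−236 mV) that hands ~18 kJ to the
archaeon and ~21 kJ to the sulphate reducer.  The archaeon translocates a
net 0.70 charges per methane (FPO and RNF pump outward; HDR and MTR spend
membrane potential inward to activate methane), which at 3 H+ per ATP
gives Y_ATP = 0.233 and a thermodynamic efficiency near 63%.  The
sulphate reducer moves 8.93 charges gross but invests 2 ATP (8 charges) in
sulphate activation, leaving a similar net yield.  The residual drives
(4.3 and 9.0 kJ/mol) limit the rates through `F_T` = 0.45 and 0.85: the
methane-oxidation side runs at about half its kinetic ceiling.  Membrane
potentials (202 and 129 mV) and the equal uptake fluxes
(~20 mmol·g⁻¹·d⁻¹, `aomsr simulate`) emerge from the charge balance, not
from assumptions.

Other CLI entry points: `aomsr validate` (element/charge audit),
`aomsr simulate`, `aomsr mca`, `aomsr optimize`, and `aomsr acceptance`
(prints a table of desk-checkable identities).

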