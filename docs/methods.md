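# Methods

## The model

`quorumfate` simulates a mammary epithelial monolayer as a hybrid cellular
automaton: a 40x20 hexagonal grid wrapped into a torus (800 sites, each
with exactly six neighbours, no edges), whose sites are empty, hold a stem
cell (SC), or hold a differentiated cell.  Every stem cell carries a
deterministic intracellular signalling system; all stochasticity lives at
the tissue level (seed placement, daughter placement, update order).

### Intracellular signalling

Seven coupled ODEs per stem cell, all regulatory couplings saturating Hill
curves (increasing curves rise from 0 to `vmax`, decreasing curves fall
from `vmax` to 0, both halving at `half_sat`):

    W  = S_w(W_env) * I_d(Dkk_env)                  Wnt signal intensity
    K' = a_K(L) - d_K K                             secreted Dkk1
    L' = W * g_E(B) - d_L L                         activated LEF/TCF
    E' = a_E(L) - d_E E                             total E-cadherin (a_E decreasing)
    P' = a_P(L) - d_P P                             proliferation factor
    N' = sigma_N - d_N(L) N                         Notch receptor (d_N decreasing)
    N* = min(N, S)                                  activated Notch
    H' = a_H(N*) - d_H H                            HES
    D' = a_D(H) - d_D D                             differentiation factor (a_D decreasing)

Micro-environmental inputs, frozen over each 1 h tissue step:

* `W_env` — ambient Wnt, a global constant (no Wnt secretion dynamics).
* `Dkk_env` — exogenous bath Dkk1 (ng/mL, step function in time) plus the
  cell's own and its stem neighbours' secreted Dkk1.  Secretion is
  converted to a close-environment concentration as
  `ng_per_model_unit * pericellular_factor * (K_self + sum K_neighbours)`:
  the bulk conversion (2.01 ng/mL per model unit, derived below) times a
  dimensionless pericellular enrichment.  Freshly secreted ligand is
  sensed at the membrane before dilution into the bulk medium; autocrine
  and juxtacrine concentrations exceed the bulk value by roughly an order
  of magnitude, and the calibrated enrichment (12.47) is what makes the
  local Dkk1 feedback a functioning quorum signal while the bulk unit
  stays anchored to the ELISA measurement.
* `B` — bound E-cadherin: per direction `kappa * min(E_self, E_i)` for an
  occupied neighbour (current level for stem neighbours, the frozen level
  for differentiated ones), summed over the six directions.
* `S` — available DSL: a constant `dsl_level` per living (stem or
  differentiated) neighbour.  DSL presentation is not dynamically
  regulated; the main regulatory route from LEF/TCF to Notch activity is
  the inhibition of Notch receptor degradation.

Eq. composition choices where the wiring is qualitative: the two Wnt
factors combine multiplicatively (either saturating ligand loss or
saturating inhibition can shut the signal off alone), and the E-cadherin
gate multiplies the Wnt drive of LEF/TCF activation for the same reason.

### Fate rules

* **Differentiate** when `D >= C_M` (takes precedence over everything).
* **Divide** symmetrically when `P >= C_P`, at least one neighbouring site
  is vacant, and at least one cell cycle `tau` has passed since the last
  division.  The daughter lands on a uniformly random vacant neighbour;
  both cells keep the mother's state with `P` reset to 0 (division
  consumes the trigger) and the division clock restarted.
* **Quiescent** otherwise — including the crowded case (`P >= C_P`, no
  vacancy), which is the density feedback that halts growth at confluence.
  Quiescent cells keep integrating their ODEs.

Differentiated cells are inert: they present their E-cadherin and DSL at
the values frozen at the moment of differentiation, stop secreting Dkk1,
and die after a lifespan `phi`, freeing the site.  There is no stem-cell
death and no asymmetric division.

### Update loop

Per 1 h tissue step: (1) compute all inputs from a synchronous lattice
snapshot; (2) advance every stem cell by RK4 with inputs frozen;
(3) execute differentiations, then divisions in uniformly random order
(random order arbitrates competition for shared vacancies; a loser stays
quiescent); (4) execute scheduled deaths.  Everything is a deterministic
function of one `numpy.random.Generator`.  Seeded cells start at a
uniformly random phase of the division cycle (clock set back by up to
`tau`); a cycle-synchronised inoculum is an artefact that drives
tissue-wide division waves.

## Emergent behaviour and calibration

The shipped parameter set (`params/default.yaml`) was produced by the
package's own calibration procedure against four targets: (i) tissue
seeded with 36 SCs survives to a dense steady state; (ii) the exogenous
Dkk1 threshold sits near 13 ng/mL; (iii) each 20% oncogenic defect
multiplies the steady SC count 2-4x; (iv) the bulk unit conversion
re-derives to about 2.01 ng/mL per model unit.  The calibration is
staged and exploits two exact invariances:

* scaling the Dkk1-inhibition half-saturation and the pericellular factor
  together leaves untreated dynamics bit-identical while sliding the dose
  threshold linearly;
* scaling the Dkk1 synthesis rate and the pericellular factor inversely
  leaves all dynamics invariant while moving the re-derived bulk unit,
  so the unit fixed point can be solved exactly last.

With these defaults the untreated tissue self-organises into a churning
mosaic: crowded interior cells slowly lose LEF/TCF (adhesion gating plus
local Dkk1 tone), their Notch receptor decays, HES falls, and the
differentiation factor crosses `C_M` after a long, heterogeneous delay;
space freed by differentiated-cell death is retaken by division of cells
near vacancies.  The steady state holds roughly 300 stem cells among
roughly 670 occupied sites.  The local secreted-Dkk1 tone is the quorum
stabiliser — stem-rich neighbourhoods are pushed toward differentiation,
stem-poor ones are relieved — and removing it collapses the mosaic into
synchronised extinction waves.

A 48 h Dkk1 pulse acts on the sparse, freshly seeded tissue: below the
threshold, clones establish mutual DSL contact before their
differentiation clocks run out and the tissue later converges to the same
steady state (low doses sometimes transiently *increase* SC counts);
above it, division licensing is suppressed long enough that clones
differentiate before clustering, and the replicate goes extinct.  The
dose-response of the 3-month SC count is therefore a clone-establishment
race, and its threshold is sharp because a replicate survives iff any of
its 36 clones does.

Oncogenic scenarios (20% increases in Notch synthesis, ambient Wnt, or
the E-cadherin half-saturation of the LEF/TCF gate) push crowded cells
below the differentiation bifurcation: the mutant tissue stops churning
and fills the lattice, a 2-4-fold SC increase over normal.

## Unit calibration

The reference measurement is 38432 pg/ml of Dkk1 conditioned by 1e5 cells
in 200 µl over 24 h, i.e. a representative medium volume of 2e-3 µl per
cell.  Re-execution in the model: 50 untreated replicates are run to
steady state (a guard rejects runs whose mean SC trajectory drifts more
than 5% over the last three days); the medium volume is 2e-3 µl times the
mean total cell count; the mean total secreted Dkk1 (model units, over
stem cells) per that volume is equated to 38.432 ng/mL, giving ng/mL per
model unit.  The shipped `ng_per_model_unit = 2.01` is the fixed point of
this procedure under the shipped dynamics.

## Parameters that matter most

| parameter | default | units | role |
|---|---|---|---|
| `wnt_ext` (W0) | 1.0 | level | ambient Wnt; scaled by `mu_wnt` |
| `dkk_inhibition_curve` | K=21.25, n=6 | ng/mL | dose sensitivity; sets the ~13 ng/mL threshold |
| `lef_ecad_curve` | K=14.9, n=2 | level | adhesion gating of LEF/TCF; crowding feedback |
| `notch_deg_curve` | vmax=0.05/h, K=0.9 | /h | Wnt-Notch coupling; crowding -> Notch decay |
| `hes_synth_curve` | K=2.4, n=2 | level/h | position of the differentiation bifurcation |
| `pf_threshold` (C_P) | 5.2 | level | division licensing; with the steep PF curve it makes early divisions dose-sensitive |
| `df_threshold` (C_M) | 8.55 | level | differentiation commitment |
| `tau` | 24 | h | cell-cycle refractory period |
| `phi` | 168 | h | differentiated-cell lifespan; also the inertia of the stem/space cycle — longer lifespans give large synchronised oscillations |
| `dsl_level` | 1.2 | level | DSL per living neighbour; small clones are DSL-starved |
| `pericellular_factor` | 12.47 | — | close-environment enrichment of secreted Dkk1 over bulk |

All rate constants are the package's own calibrated values; the published
description of this system fixes the wiring and the qualitative shapes
but not the constants, so no quantitative agreement of individual rate
constants with any laboratory measurement is implied.

## Numerical choices

* Fixed-step RK4 with inputs frozen per tissue step; levels clipped at
  zero after each substep (the clip never activates for the default rates
  at the default steps; it guards pathological parameter sets).  The
  single-cell API uses dt = 0.1 h; tissue experiments default to five
  substeps per 1 h step (dt = 0.2 h), which is statistically
  indistinguishable from dt = 0.1 h for the shipped rates (fastest rate
  1/h; step-halving moves a 24 h endpoint by under 1e-4 relative) and
  halves the cost of a 50-replicate sweep.
* The compiled (numba) replicate engine and the pure-Python reference
  implement the identical protocol, share the generator draw sequence and
  the floating-point expression forms, and are asserted bit-identical on
  full trajectories in the test suite.
* Replicate seeds derive from `(master_seed, dose value, replicate
  index)` via `numpy.random.SeedSequence`: sweeps are order-independent
  and any replicate is individually re-runnable.
* Ties: simultaneous threshold crossing resolves to differentiation
  (anti-proliferative); competition for a shared vacancy is resolved by
  the random execution order; a division whose last vacancy was taken is
  cancelled for that step.
* Degenerate inputs: an empty lattice is a fixed point; a cell with no
  living neighbours has `B = S = 0`; extinction (no stem cells) is
  absorbing and the engine then only processes scheduled deaths.

## What the simulations do and do not show

The generator *is* the study design: everything here is synthetic tissue
under the stated rules.  Passing tests show that the implementation
realises the intended mechanism — threshold-shaped dose response via
clone-establishment failure, quorum-stabilised SC density, mutation-driven
escape — under the calibrated stand-in parameters.  They do not show that
the real signalling network has these rate constants, nor do they
reproduce any wet-lab measurement beyond the qualitative biphasic pattern;
mammosphere counts and flow-cytometry tables are outside the model.  The
dose threshold and fold-changes are properties of the calibrated default
set and move with it.

## Known limitations

* No spatial diffusion of ligands: exogenous Dkk1 is well mixed, secreted
  Dkk1 is strictly local, ambient Wnt is constant.
* No extracellular decay of secreted Dkk1 beyond the intracellular
  first-order term.
* DSL presentation is constant per living cell rather than LEF/TCF
  regulated.
* Differentiated cells neither proliferate briefly nor change their
  presented ligands; stem cells never die.
* The replicate-to-replicate spread of the steady SC count is sizeable
  (SD ~15% of the mean): single replicates are not meaningful estimates
  of the dose response; the 50-replicate protocol is.
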