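# Methods

## Scope and structure

`thrombosim` simulates intravenous thrombolysis of a fully occluding clot
in a cerebral artery as two one-way-coupled sub-models:

1. a **systemic PK-PD model**: eight stiff ODEs for the drug in central and
   peripheral compartments plus six fibrinolytic proteins (plasminogen PLG,
   plasmin PLS, α2-antiplasmin AP, α2-macroglobulin MG, fibrinogen FBG,
   PAI-1) in plasma;
2. a **local clot model**: a 1D porous slab with Darcy flow, conservative
   finite-volume convection–diffusion of seven free species, surface
   binding of activator/plasminogen/plasmin on a shared fibrin site pool,
   bound-phase plasmin generation, and plasmin-driven site degradation.

The systemic central-compartment trajectory supplies the clot's inlet
Dirichlet condition; local consumption does not feed back (the clot volume
is negligible against the plasma pool).

## Systemic model

State: Cc, Cp (drug, μM) and the six proteins. Rates:

- plasminogen activation r_act = k_cat·Cc·C_PLG/(K_M + C_PLG); the
  activator is catalytic and not consumed;
- PAI-1 inhibition r_PAI = k_PAI·Cc·C_PAI, consuming drug and PAI-1 1:1;
- plasmin neutralisation by AP and MG, second-order, consuming both
  partners;
- fibrinogenolysis r = k_fbg·C_PLS·C_FBG, catalytic in plasmin;
- first-order elimination k_el,i per species with homeostatic secretion
  S_i = k_el,i·C_init, so the drug-free pre-dose state is steady by
  construction. Endogenous tPA/uPA (alteplase and urokinase carry nonzero
  baselines) are maintained by S_PA = k_el·C0; for these drugs the
  baseline PAI-1 reaction makes the pre-dose state only approximately
  steady — the imbalance is orders of magnitude below dose-driven dynamics.

Dose regimens are piecewise-constant infusions at their clinically stated
durations (boluses are 5 s–2 min infusions, never impulses). The
integrator (LSODA, rtol 1e-8, atol 1e-15) is restarted at every segment
boundary so the discontinuous source never degrades error control; output
sampled every 5 s. PAI-1 falls by up to seven orders of magnitude during
therapy, hence the very small absolute floor. Undershoots below zero are
floored only within the solver tolerance band; anything larger raises an
error with the time and state attached.

The default observation horizon is 4 h for every preset. The local march
stops at clot dissolution, so the horizon mainly controls the systemic
safety read-outs: the slow-clearing agents (urokinase in particular, with
k_el = 4.06e-4 s⁻¹ and strong peripheral distribution) continue to build
their systemic lytic state for hours after the clot is gone, and a shorter
window would truncate the fibrinogen nadir.

## Local model

Grid: 50 cells over a 10 mm clot (Δx = 0.2 mm), optionally preceded by a
clot-free entry region (default none). Free pore-fluid species: drug, PLG,
PLS, AP, MG, FBG, PAI-1 (MG is carried along so the pore fluid runs the
same plasma reactions as the systemic model). Bound species: activator·F,
PLG·F, PLS·F on the shared pool n_total(x,t).

**Flow.** Permeability per cell from the Davis fibrous-media correlation
k = r_f²/[16(1−ε)^1.5(1+56(1−ε)³)]. The velocity is uniform (1D
incompressible); the default pressure mode holds the gradient across the
*intact* clot at `dp_per_length`, composing intact-cell resistances
harmonically — fully lysed cells drop out of both resistance and length,
so the flow rises moderately as the clot resolves. A `total` mode (fixed
total Δp over the whole domain, strong recanalization acceleration) is
available by config. A numerical cap u_max = 2 cm/s applies only once the
channel has effectively reopened.

**Transport.** Conservative finite volume: first-order upwind convection
(flow is unidirectional), central-difference diffusion of the pore
concentration with the porosity folded into the diffusive flux, inlet
Dirichlet from the systemic trajectory, advective outflow with zero
diffusive flux distally. The step subdivides internally to respect CFL and
diffusion limits. Diffusion acts on the free-phase concentration (the
physically conventional form for porous-medium solute transport).

**Kinetics per cell** (explicit sub-stepping under operator splitting; the
sub-step shrinks so no quantity loses more than 20% of its value per
sub-step, which preserves positivity without clipping mass away):

- adsorption/desorption of drug (k_a, k_d from the drug tables; identically
  zero for urokinase), plasminogen and plasmin on free sites;
- bound-phase plasmin generation, Michaelis–Menten in bound plasminogen
  with K_M scaled by (1−ε_clot); driven by bound activator for the tPA
  family, by the free urokinase concentration for the non-binder;
- the full plasma reaction set in the pore fluid (activation, PAI-1
  inhibition of free drug, plasmin neutralisation, fibrinogenolysis);
  bound plasmin is protected from AP/MG by default (configurable);
- site degradation ∂n_total/∂t = −k_deg·γ·n_PLS,bound, floored at zero;
  bound species are released to the pore fluid in proportion to the site
  loss (mass conservation), and porosity closes linearly,
  ε = 1 − (1−ε_clot)·n_total/n_total(0), with εC held fixed across the
  porosity change.

**Initial state.** Pore fluid at the systemic baseline but with zero
activator (a resting clot sees no active endogenous activator — plasma uPA
is predominantly zymogen and baseline PAI-1 scavenges what little active
enzyme reaches the clot); bound plasminogen at Langmuir equilibrium with
baseline plasma (plasminogen is incorporated during clot formation). An
optional drug-free spin-up is provided for non-equilibrium custom
configurations; at the defaults it is an exact no-op.

## Read-outs

- **Lysis time**: first time every clot cell is below a threshold fraction
  (default 5%) of its initial binding sites; crossings are interpolated
  between stored frames (15 s cadence).
- **Activation time**: first time sites at the monitoring position
  (default 5 mm from the clot face) fall 10% below initial.
- **Front lysis duration**: activation-to-completion interval at the
  inlet-face cell.
- **Exposure**: trapezoidal AUC of the central drug concentration.
- **Safety**: systemic fibrinogen nadir (absolute and fraction of
  baseline; the hemorrhage-risk proxy), minimum systemic PAI-1 (inhibition
  resistance), clot-phase PAI-1 at completion.

All metrics are pure functions of the stored records; recomputation from
the CSV outputs is exact.

## Parameter provenance and the calibration surface

Drug-specific kinetic and PK constants (initial concentration, plasma
K_M/k_cat, k_PAI, k_el, k_cp, k_pc, V_c, fibrin k_a/k_d/K_d, clot-phase
K_M/k_cat) are transcriptions of published in-vitro and clinical values
and are never tuned. Two unit ambiguities in the sources are resolved as
documented choices: k_PAI is taken as μM⁻¹s⁻¹ for every drug (one source
column prints a bare μM⁻¹), and clot-phase K_M/k_cat rows without printed
units are taken as μM and s⁻¹.

Everything else lives in `data/calibration.yaml` and is the declared
calibration surface — auditable, swappable, and the only thing adjusted to
reproduce the published scenario behaviour:

| group | defaults | rationale |
|---|---|---|
| protein baselines | PLG 2.2, AP 1.0, MG 3.0, FBG 8.0, PAI-1 4e-4 μM | standard plasma values |
| protein turnover | days-scale for PLG/AP/MG/FBG; PAI-1 2e-4 s⁻¹ | PAI-1 decays by latency conversion (t½ ≈ 1 h), which both replenishes inhibition and steadily scavenges slow-clearing activators |
| auxiliary kinetics | PLS+AP 10, PLS+MG 0.1, PLS+FBG 0.1 μM⁻¹s⁻¹ | fast 1:1 antiplasmin capture; macroglobulin as slow backup; catalytic fibrinogenolysis |
| molecular weights | 59.05/58.95/39.57/33.0 kDa | reteplase fixed by its 10 U = 17.4 mg equivalence; urokinase as the low-molecular-weight therapeutic form |
| clot geometry | 10 mm, ε 0.75, r_f 200 nm | coarse fibrin-rich occlusion |
| flow | Δp/L 4.6e5 Pa/m (~35 mmHg/cm), μ 1.3e-3 Pa·s | full arterial occlusion; plasma (not whole blood) permeates the pores; gives ~10 min plasma transit through the clot, putting activation in the observed 12–20 min range |
| sites | n_total 1.0 μM accessible sites; PLG·fibrin K_d 20 μM; PLS·fibrin K_d 0.5 μM | only a small fraction of fibrin monomers is accessible to the lytic enzymes; plasminogen binds intact fibrin weakly, plasmin tightly via its kringles |
| lysis | k_deg·γ = 0.625 s⁻¹ (γ = 10) | sets the front sharpness and overall lysis scale |
| thresholds | lysis 5%, activation 10% | operational definitions of "lysed" and "begins to degrade" |

## What the presets do and do not reproduce

At the shipped defaults the four presets give (lysis / activation at 5 mm /
front duration, minutes): alteplase 24.2 / 14.2 / 2.2, tenecteplase
25.9 / 14.1 / 2.6, urokinase 23.8 / 13.3 / 2.0, reteplase 99.4 / 19.6 /
39.5. The qualitative pharmacology is reproduced: urokinase completes
fastest but causes the deepest systemic fibrinogen depletion and is
inhibited hardest by PAI-1; tenecteplase matches alteplase's efficacy at a
quarter of the dose with better fibrinogen sparing and by far the best
PAI-1 resistance; reteplase is several-fold slower but leaves fibrinogen
untouched; lysis-time ordering is strict and stable across completion
thresholds of 1–10%.

Two related features are **not** reproduced and are considered structural
limits of this model reduction rather than calibration gaps. First, the
activation-time ordering at 5 mm: here urokinase activates slightly
*earlier* than the tPA-family drugs, because its transport is not retarded
by fibrin binding and its clot-phase catalytic constant (2.6 s⁻¹, the
largest of the four) keeps its local kinetics within about a factor of two
of alteplase's bound-activator pathway everywhere in the admissible
parameter space; the saturation window K_M(1−ε) that would slow it further
trades directly against reteplase ever completing. Second, and for the
same reason, the front-duration contrast between drug classes is
compressed: the tPA-family fronts are sharp (~2 min) as expected, but the
urokinase front is similarly sharp rather than ~10 min, and the reteplase
front, while much longer (~40 min), does not exceed an hour. Reproducing
those contrasts would require bound-phase intermediate-complex kinetics
beyond the lumped Michaelis–Menten forms implemented here.

## Numerical choices

- Spatial resolution 50 cells; halving Δx moves lysis times by ~2% and the
  scheme converges first-order (upwind). All shipped numbers are defined
  at the default grid.
- Outer splitting step ≤ 2 s; transport sub-steps enforce CFL ≤ 0.8 and
  diffusion number ≤ 0.25; kinetics sub-steps are positivity-limited.
- Integrator tolerance halving moves systemic finals by < 0.1%.
- Degenerate inputs: zero-dose regimens are rejected at construction
  (a regimen must deliver mass); a drug-free inlet leaves the clot intact
  indefinitely; fully degraded cells are clamped open (ε = 1, no bound
  mass) and excluded from the Davis correlation, which is singular at
  ε = 1.
- Determinism: there is no randomness anywhere in the pipeline; identical
  scenarios produce byte-identical outputs.

## Known limitations

- 1D, single homogeneous clot, no patient-specific vasculature, pulsatile
  flow, mechanical fragmentation or embolization.
- One deterministic 80 kg patient; no inter-individual PK variability.
- One-way systemic→local coupling.
- The fibrinogen read-out is a risk proxy; no clinical outcome model.
- The calibration surface is tuned to a single published scenario family;
  transferring the defaults to other clot geometries or doses should be
  done with the sensitivity of activation/lysis times to Δp/L, n_total and
  k_deg·γ in mind.
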