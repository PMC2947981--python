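# Methods

## Model

`coagkin` integrates a homogeneous, well-mixed mass-action network of
blood coagulation in molar units and seconds. Two canonical builds are
provided by `coagkin.library`:

* **Fixed-rate extrinsic network** (`build_hockin_mann`): 34 species and
  27 reactions — TF·VIIa-initiated activation of IX/X, intrinsic tenase
  (IXa·VIIIa), prothrombinase (Xa·Va), meizothrombin, and inhibition by
  TFPI and ATIII. Rate constants are used as tabulated; platelets are
  implicitly fully activated at *t* = 0. An optional variant
  (`with_detection=True`) appends the fluorogenic-substrate chemistry so
  conversion metrics can be computed for this model too.
* **Platelet–plasma network** (`build_platelet_plasma`): 76 species and
  57 reactions. Additions over the fixed-rate core: a first-order XIIa
  source (XII → XIIa at 5×10⁻⁴ s⁻¹, a coarse-grained description of
  surface contact activation leaking past CTI), XIIa autoactivation,
  reciprocal XII/prekallikrein/kallikrein activation, XI activation by
  XIIa and thrombin plus XI autoactivation, inhibition of the contact
  proteases (CTI, C1-inhibitor, ATIII, α₁-antitrypsin, α₂-antiplasmin),
  TF-independent VIIa activity on IX and X, thrombin detection chemistry
  (Boc-VPR-MCA → AMC), and an eight-reaction fibrin module in which
  fibrinogen acts as a competing thrombin substrate and fibrin–thrombin
  complexes are irreversibly trapped with ATIII.

Binding–catalysis reactions are expanded into explicit elementary steps:
association `k_on·[E][S]`, dissociation `k_off·[ES]`, turnover
`k_cat·[ES]`. Where a source lists a Michaelis/dissociation constant
instead of an off-rate, the off-rate is reconstructed as
`k_off = K_m·k_on − k_cat` with diffusion-limited `k_on = 10⁸ M⁻¹s⁻¹`
(`km_to_off_rate`); the builders' constants round-trip to the tabulated
K_m/K_d values within 5% (rounding of the printed tables), which the test
suite asserts reaction by reaction.

Released fragments that nothing downstream consumes — fibrinopeptides A/B,
the fibrin-II dimer, inhibited kallikrein — are not carried as dynamic
state. They are recorded per reaction (`untracked_products`) and
integrated as auxiliary accumulators so that moiety conservation can be
checked exactly.

## Platelet activation state

Platelet procoagulant function is a single dimensionless fraction ε
(interpreted as normalized phosphatidylserine exposure). Its ceiling is a
Hill function of the running maximum M of free thrombin, and ε relaxes
toward the ceiling with first-order kinetics:

    ε_max(M) = ε₀ + (1 − ε₀)·Mⁿ/(EC50ⁿ + Mⁿ)
    dε/dt = k_act·(ε_max − ε),  ε(0) = ε₀

| parameter | default | units | rationale |
|---|---|---|---|
| ε₀ | 0.01 | – | 1% basal PS exposure on resting platelets; set to 1.0 to emulate agonist pre-activation |
| k_act | 0.005 | s⁻¹ | 1/k_act = 200 s, the platelet calcium-mobilization time scale |
| n (Hill) | 3 | – | see calibration below |
| EC50 | 2.169 | nM | derived from the saturation constraint |
| mIIa weight | 0 | – | only free IIa drives activation; meizothrombin weight is configurable |

**Calibration of the unmeasured Hill pair (n, EC50).** The PS-exposure
dose response is known only graphically, so the defaults are fixed by the
model's own calibration constraints: ε_max(0) = ε₀; ε_max must first
reach 0.99 at 10 nM thrombin (full activation); and ε_max must stay near
basal at ≤ 100 pM (circulating thrombin must not activate platelets).
With n = 3 the second constraint gives EC50 = 10 nM/98^(1/3) ≈ 2.169 nM
exactly, and ε_max(100 pM) ≈ 0.0101. End-to-end initiation times are
insensitive to this pair over n = 3…6 (the pre-burst trajectory runs at
ε ≈ ε₀ and the burst itself is fast), so the smallest integer exponent
satisfying all constraints is used. `fit_hill` re-estimates (n, EC50)
from user-supplied PS-exposure data when available.

**Running maximum.** M is integrated alongside the network with
dM/dt = max(0, d[IIa]/dt) and M(0) = [IIa](0). For a single-peaked
thrombin transient this equals the running maximum exactly: M tracks IIa
while it rises and freezes at the peak, so platelets stay activated when
thrombin declines. (A crest-gated variant `dM = dIIa·1[IIa ≥ M]` is
formally tighter but places a chattering discontinuity exactly on the
solution path and defeats the stiff integrator's Newton iteration.)

**Rate modulation.** For each membrane-dependent reaction the effective
dissociation rate is `η·k₋₁/ε`, where η converts the tabulated reference
constant to its fully-activated (ε = 1) value. ε-coupling applies exactly
to the reactions carrying an η entry in the embedded table (ids 1, 2,
6–8, 11–13, 17, 18, 20, 21, 30–32, 39, 45–47, 49); the VIIIa
subunit-dissociation reaction (13) is written complex-first in the source
table, so its modulated constant is the tabulated forward rate — after
normalization the modulated step is still the physical unbinding step.
Catalytic rates are never modulated (loosely bound complexes are assumed
rarely to turn over). In `lipidated_tf_mode` the TF-dependent reactions
(1, 2, 6–8, 21) are frozen at their ε = 1 rates: exogenous TF arrives on
lipid vesicles that provide their own procoagulant surface. Scenarios
that add TF use this mode by default in the experiment runners.

## Scenarios

A `Scenario` maps the tabulated initial conditions onto one well:

1. CTI is set to its phlebotomy-syringe concentration (default 4.2 µM);
2. every concentration is divided by `dilution_factor` (default 5, the
   plate protocol);
3. optionally the fluorogenic substrate is re-pipetted to its tabulated
   10 µM in-well value (`substrate_at_well_conc`, default off — the
   default follows the stated simulation protocol of diluting *all*
   species, although the experimental protocol pipettes the substrate
   into the well after dilution; the switch exposes the discrepancy);
4. knockouts scale initial concentrations (0.01 emulates immunodepleted
   plasma with <1% residual activity);
5. exogenous additions are applied at final in-well concentration, never
   diluted (dose axes of titration experiments are in-well values).

The order (dilution, then additions) is pinned by tests.

## Numerics

* Integrator: `scipy.integrate.solve_ivp`, LSODA by default (BDF/Radau
  selectable), relative tolerance 10⁻⁷ and absolute tolerance 10⁻³⁰ M —
  species span sub-femtomolar to tens of micromolar. An analytic dense
  Jacobian is supplied (mass action is bilinear; the activation rows add
  the Hill derivative and a relu gate); this is roughly an order of
  magnitude faster than numerically differenced Jacobians and avoids
  their step-size collapse near the thrombin burst.
* Output is resampled to a uniform 60-s grid (one plate read per minute);
  metrics are computed from the resampled series so simulated and
  measured traces are processed identically. A 4-h horizon is the
  default, matching the assay.
* T_i (threshold mode) is the first crossing of C = 0.05, linearly
  interpolated between reads; crossings inside the first read interval
  are flagged `pre_first_read` (the experimental dead time between
  phlebotomy and the first read), not masked. The alternative `d2max`
  metric smooths C with a 5-read moving average, takes the central second
  difference, and reports its maximizer; it returns none when no positive
  acceleration exists away from the smoothing edges. Window and smoothing
  are implementation choices (the experimental metric's smoothing is not
  specified); for a logistic trace the 5% crossing precedes the
  second-derivative maximum (which sits at ~21% conversion), and the
  tests pin that ordering.
* The free-Xa "early plateau" of TF-stimulated whole blood is read as the
  flattest point of log[Xa] (minimum of d log c/dt) between the first
  read and the time ε crosses 0.5.
* Local sensitivities are central differences of ln T_i with respect to
  ln k under multiplicative perturbation (default ±5%), with a flagged
  one-sided fallback when a perturbed run never initiates.
* Conservation of the TF, CTI, fluorogenic-substrate and fibrinogen
  moieties holds structurally (S·w = 0) and to ~10⁻¹⁴ relative along
  trajectories; concentrations stay non-negative to within
  10⁻¹²·(species maximum). Identical inputs give identical outputs; T_i
  moves by < 0.1 min when the relative tolerance is tightened to 10⁻⁹.

## Design choices in open territory

* **XI autoactivation rate (reaction 40).** The only literature estimate
  (3.19×10⁶ M⁻¹s⁻¹) comes from a model that attributes all
  non-XIIa-mediated XI activation to a single mechanism; since this
  network also carries thrombin feedback on XI, the default is 4-fold
  lower (7.98×10⁵), with the original value available as a builder
  override.
* **Fixed-rate limit.** `to_hockin_mann_limit` disables every extension
  (XIIa source off; contact species, fibrinogen and substrate zeroed;
  TF-independent VIIa and cofactor-free IXa/Xa routes off; ε frozen at 1;
  η forced to 1) and then reproduces the 34-species model's 5 pM TF
  trajectory to ~10⁻⁷ relative. Zeroing reactions 46–49 is required: at
  full activation the VIIa·IX complex alone sequesters most free VIIa
  and shifts the burst by several minutes.
* **Detection chemistry** is thrombin-specific (meizothrombin does not
  cleave the substrate); a configurable weight exists for the activation
  signal but not for the substrate.

## What the simulations do and do not show

The model reproduces the qualitative physiology it was built for:
initiation of contact-inhibited blood without TF on the hour scale
(resting T_i ≈ 88 min at default parameters, within the accepted 60–90
min window but above the ~75 min center), a several-fold drop on platelet
pre-activation (T_i ≈ 13 min), nanomolar thrombin at the 5% conversion
crossing, monotone dose responses for TF over three decades and for
platelet pre-activation level, and a free-Xa plateau of tens of pM
followed by a ~3.5-order burst under 5 pM TF.

Known deviations, quantified by the test suite:

* **Added Xa responds gradedly, not switch-like.** With the tabulated
  constants, 10 pM added Xa roughly halves T_i by self-igniting the
  V → Va → prothrombinase feedback while platelets are still resting
  (the ε-coupling of the Xa–TFPI reaction weakens resting TFPI inhibition
  to K_d ≈ 40 nM). The expected behavior — negligible effect at 10 pM,
  saturation at 100 pM — is asserted by an end-to-end test that currently
  fails, and is insensitive to every legitimately free parameter; the
  published ODE listing behind the tabulated constants may differ from
  what the printed tables imply.
* Added Va changes T_i by up to ~10% at 4 nM (nominally "negligible").
* The post-initiation burst is sharper than real propagation-phase
  kinetics; no prothrombinase-inhibition mechanism is modelled, so the
  model is an indicator of initiation timing, not of the full
  thrombogram.

The synthetic plate traces (`coagkin.io.synth_trace`) are logistic
conversion curves with Gaussian read noise: adequate for validating
metric extraction and round-trips, but they do not emulate drift,
saturation nonlinearity or well-to-well calibration variance of real
plate readers, so passing those tests says nothing about such artifacts.

Out of scope by design: explicit platelet binding-site saturation and
bulk/surface partitioning, flow and spatial gradients, antibody binding
kinetics (knockouts are concentration edits), agonist-specific signalling
(pre-activation is ε₀ = 1), APC/thrombomodulin pathways, and
thermodynamic-cycle consistency checking.
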