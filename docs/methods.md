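# Methods

`coagsim` couples two deterministic mass-action ODE models of concizumab
action in hemophilia A: a well-mixed **compartment model** of the antibody
binding the two TFPI isoforms, and a **flow-mediated reaction-zone model**
of TF-initiated coagulation over a small (10 × 10 μm) injury.  The
compartment model's steady state supplies the flow model's plasma initial
conditions; everything downstream (thrombin time courses, lag times,
mechanism knockouts, sensitivity sweeps) is forward simulation.

Internal units are nM and seconds everywhere; bimolecular rate constants
quoted on the molar scale are converted by 1e−9 at network construction.
Concentrations and times are serialized in nM and minutes.

## Compartment model

Concizumab (C) is a bivalent antibody against the Kunitz-2 (K2) domain of
TFPI.  Five reversible reactions describe its binding to plasma TFPIα
(2.5 nM total) and endothelial TFPIβ (18 nM effective, no geometry
correction), including the ternary bridge TFPIα:C:TFPIβ that sequesters
plasma TFPIα onto the endothelium:

| reaction | rates |
|---|---|
| C + TFPIα ⇌ C:TFPIα | kα⁺ = 4.48e6 M⁻¹s⁻¹, kα⁻ = 1e−4 s⁻¹ |
| C:TFPIα + TFPIα ⇌ TFPIα:C:TFPIα | kα |
| C + TFPIβ ⇌ C:TFPIβ | kβ⁺ = 8.21e5 M⁻¹s⁻¹, kβ⁻ = 1e−4 s⁻¹ |
| C:TFPIα + TFPIβ ⇌ TFPIα:C:TFPIβ | kβ |
| TFPIα + C:TFPIβ ⇌ TFPIα:C:TFPIβ | kα |

No statistical factor is applied to the second TFPIα-binding step beyond
the printed rate.  Clearance and metabolism of antibody-TFPI complexes are
outside scope.

**Steady-state definition.**  The system is declared steady when no
species changes by more than 0.2 nM across a trailing 5-minute window
(sampled every 30 s; 48 h horizon; LSODA, rtol 1e−10 / atol 1e−13).  This
absolute, plot-resolution notion of "negligible change" matters: the model
has a fast phase (antibody capture, minutes) and a very slow internal
redistribution between TFPIα:C:TFPIα and TFPIα:C:TFPIβ on the
kα⁻ ≈ (2.8 h)⁻¹ timescale that barely moves the plasma pools.  The
physiological/clinical reading is the post-distribution quasi-steady state
(detected at ≈16 min for the 21.5 nM dose), which yields the partition
15.52 / 1.85 / 0.54 nM and 74% TFPIα sequestration.  Driving the system to
strict equilibrium instead (a tight relative tolerance, exposed via
`rel_tol`) shifts the ternary pool to 1.94 nM while leaving the plasma
concizumab pool essentially unchanged; both read-outs are available, and
tests pin each against its own oracle.  A consequence worth knowing: the
dose inversion to a 4.00 nM plasma pool returns 21.36 nM, not exactly
21.5 — at 21.5 nM the quasi-steady plasma pool is 4.13 nM, which is also
what the 15.52 + 1.85 + 0.55 partition sums to under dose conservation, so
the two published read-outs ("dose 21.5" and "plasma 4 nM") are consistent
only to that rounding.

**Dose inversion** bisects the monotone dose → plasma-concizumab map to a
0.01 nM dose tolerance.  **Flow inputs**: plasma TFPIα-containing species
are scaled by 0.2 (only ~20% of plasma TFPIα circulates free and
full-length; the lipoprotein-bound remainder is neglected), free
concizumab passes unscaled, endothelial species are dropped — TFPIβ acts
on the flow model solely through these plasma levels.

## Flow-mediated model

The reaction zone (RZ) is a well-mixed slab above the injury; a single
first-order mass-transfer rate (k_flow = 0.0025 s⁻¹ for proteins,
0.5 s⁻¹ for platelets) exchanges every plasma species with bulk.  TF
surface density (fmol/cm²) is converted to an RZ concentration by a single
calibrated factor in the parameter file.  Three platelet classes are
modelled: quiescent in plasma, adhered to the subendothelium (these are
activated by contact and progressively *cover* the injury, attenuating
every subendothelial reaction by 1 − coverage), and aggregate-bound
platelets activated by contact with active platelets or — above a hard
1 nM thrombin threshold — by thrombin.  The threshold discontinuity is
handled by two-phase integration with event detection, so the stiff solver
never steps across the switch.  Activated platelets expose saturable
binding sites (per-platelet numbers for FXa, FIXa, FV(a)/FV-h and FVIIIa)
through which membrane chemistry proceeds: tenase (FVIIIa:FIXa) producing
membrane FXa, and prothrombinase assembled with either FVa or the
partially cleaved FV-h.

TFPIα inhibits at three locations: plasma FXa (K_D 20 pM), the nascent
subendothelial TF:FVIIa:FXa product complex (quaternary capture, 1.6e7
M⁻¹s⁻¹ / 3.3e−4 s⁻¹, plus re-binding of TFPIα:FXa to TF:FVIIa), and
platelet-bound FXa.  Its basic C-terminus also sequesters FV-h (5e7
M⁻¹s⁻¹ / 4.5e−3 s⁻¹), slowing early prothrombinase assembly.  The
concizumab extension adds the antibody's reactions with TFPIα free, bound
to FV-h in plasma and on membranes, and inside early prothrombinase; the
C:TFPIα complex retains the C-terminal FV-h interaction (a toggle exposes
the alternative).  Note the printed TFPIα-FV-h rate pair corresponds to
K_D = 90 pM although the accompanying source note says 9 pM; the printed
rates are used.

**Provenance and calibration.**  The predecessor reaction-zone model's
full supplementary parameter set was not available to this package.  The
base model here is therefore a *reduced reconstruction* (44 species): its
structure follows the description above, every concizumab/TFPI rate that
is printed is used verbatim, and the remaining ~30 parameters (tagged
`estimated` in `data/flow_base.yaml`) were set to physiological scales and
then calibrated, by coordinate descent, so that the reconstruction
reproduces the predecessor's published lag-time behaviour on the
TF × FVIII × concizumab grid and the mechanism-knockout decomposition at
TF = 9 fmol/cm².  The TFPIβ/FV-h toggles, the protein-S scaling and the
affinity sweep were *not* part of the calibration objective; their
behaviour is a genuine prediction of the reconstruction.

What the calibrated reconstruction does and does not reproduce
(hemophilia A = FVIII 0.01 nM; lag = first crossing of 1 nM thrombin,
linearly interpolated on a 1 s output grid; censored at 40 min):

* censoring structure exact: TF = 4 fmol/cm² generates <1 nM thrombin in
  40 min with and without concizumab; all TF ∈ {9, 20} runs cross;
* with concizumab: 11.1 / 4.5 min at TF = 9 / 20 (published 10.6 / 5.0);
* without: 27.2 / 5.7 min (published 35.6 / 6.3);
* normal FVIII: 16.5 / 7.5 / 4.2 min at TF = 4 / 9 / 20 (published
  13 / 7 / 3);
* knockout lags at TF = 9: 19.7 (platelet-FXa block) > 18.9 (SE block) >
  14.8 (all three) > 11.1 (concizumab) — same strict order as published
  (20.1 > 15.6 > 13.5 > 10.6) but with the two intermediate scenarios
  closer together: with the printed quaternary kinetics and 0.5 nM plasma
  TFPIα, the subendothelial brake cannot be made as dominant as in the
  original without violating other constraints;
* thrombin plateau: runs crossing early settle at 204–211 nM by 40 min
  (published band 200–300); runs crossing after ~25 min are still rising
  at 40 min (e.g. the no-concizumab TF = 9 run reaches ~17 nM), a known
  limitation — the reconstruction's post-threshold burst is
  platelet-supply-limited;
* protein S (association ×10 on the four platelet TFPIα-FXa reactions):
  abrogates thrombin generation at TF = 9 and 13 without concizumab,
  lengthens the TF = 17 lag by ~7 min, and changes with-concizumab runs by
  <0.03 min — matching the published pattern;
* affinity sweep (K_D(α) 15–100 pM × K_D(β) 100–500 pM, dose fixed at
  21.5 nM): lag varies within ~0.35 min, smoothly; plasma concizumab spans
  4.02–5.47 nM and the ternary 1.68–1.91 nM, slightly wider than the
  published 4–5 / 1.80–1.96 ranges at the K_D(β) = 500 pM corner under
  either realization of K_D (vary k_on — the default — or vary k_off).

## Scenario engine

Mechanisms are "blocked" by zeroing association rates, never by removing
species, so state-vector layout and trajectories stay comparable.  The
platelet-FXa knockout covers TFPIα binding FXaᵐ directly and within
FXaᵐ:FV-hᵐ; the two TFPIα:FV-h-mediated FXa captures belong to the FV-h
mechanism and stay active (all four scale with protein S).  Scenarios that
change the compartment world (TFPIβ absent, K_D overrides) re-run the
compartment model and the dose inversion to the fixed 4 nM plasma target;
the affinity sweep instead holds the intravascular dose at 21.5 nM, which
is what lets the plasma pool drift upward across the sweep.  K_D overrides
move the association rate with the dissociation rate fixed (mode `"off"`
is exposed), and the TFPIα affinity override is applied to both models.

## Synthetic fixtures

`synthetic` provides (a) the A + B ⇌ AB toy network whose equilibrium is
the root of a quadratic — the integrator must recover it to 1e−6 relative,
which is the core correctness check for the ODE engine; (b) log-normal
parameter ensembles (mandatory seeds, structural zeros preserved) for
robustness tests; (c) logistic thrombin curves with an analytic 1 nM
crossing for the lag metric.  These fixtures emulate the *shape* of the
real problem (stiff binding kinetics, threshold crossings), not real
plasma: passing them demonstrates numerical correctness, not biological
validity of the flow model.

## Numerical choices

LSODA with rtol 1e−8 / atol 1e−12 nM for flow runs (rate constants span
>10 orders of magnitude); halving the tolerances moves lag times by
<0.05 min.  Species order is declaration order and all pipelines are
deterministic, so reruns are bit-identical (manifests carry SHA-256
checksums).  Negative round-off concentrations are clamped to zero only in
reported output, never inside the solver state.  Mass-action sides are
limited to order ≤2 (all reactions here are at most bimolecular);
conserved-moiety pools are validated against the stoichiometry at network
construction.

## Problem sizes in the test suite

The default suite runs the compartment model at a handful of doses, the
full flow battery on the {4, 9, 20} × {1%, 100%} × {±concizumab} grid, the
six knockout scenarios, the four TFPIβ/FV-h arms at TF ∈ {5, 7, 9}, the
protein-S grid at TF ∈ {9, 17}, and a 3 × 3 affinity sweep; each flow run
integrates 40 simulated minutes of a 44-species stiff system in under a
second.
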