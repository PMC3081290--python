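# Methods

## Scope and model form

coagsim simulates the onset of blood coagulation as a deterministic
mass-action reaction network in a well-mixed volume, in base units of
mol/l and seconds. The state is the concentration vector **c** of ~60
species; the dynamics are d**c**/dt = **S** v(**c**), with **S** the
integer stoichiometric matrix and v the vector of rate-law values.
Every rate law is restricted to a signed sum of mass-action monomials
(products of rate constants and concentrations). This restriction is
deliberate: every kinetic expression in the network — irreversible
conversions, reversible binding written as kf·(∏reactants − Ki·∏products),
and the albumin-pool protein-binding forms — fits it, it makes the
right-hand side compilable to a few vectorised numpy operations, and it
lets the Jacobian be assembled analytically, which the stiff integrator
needs. There is no general kinetic-expression parser.

Spatial structure, platelets, fibrinolysis and stochastic (SSA)
simulation are out of scope; the model describes the ignition of
thrombin and fibrin generation, not clot mechanics or resolution.

## Network content and provenance

The network is assembled from well-characterised published
sub-models, re-expressed as elementary mass-action reactions:

- **Extrinsic core (32 reactions, ids R1–R32).** Tissue-factor
  initiation, Factor X/IX activation by TF–VIIa, tenase
  (IXa–VIIIa), lipid-bound prothrombinase (Xa–Va on phospholipid
  sites), TFPI and antithrombin inhibition. Rate constants keep the
  source model's k1..k42 numbering; reaction R9 (prothrombin
  activation by free Xa) carries k16. Enzyme–substrate schemes are
  split into reversible binding plus catalysis; the two directions of
  VIIIa dissociation are separate reactions. The five antithrombin
  neutralisation constants (k38–k42) are halved relative to the source
  model, whose values sit at the upper end of the measured ranges.
- **Intrinsic chain (constants Kog\*).** XIIa-catalysed XI activation,
  XIa-catalysed IX activation, slow direct X activation by IXa, the
  thrombin feedback on Factor XI, and antithrombin/C1-inhibitor-type
  neutralisation of XIa and XIIa.
- **Fibrinogen cleavage (RI).** IIa + fibrinogen → IIa + fibrin
  ("Ia"), with kcat/Km folded into a second-order constant. Fibrin and
  thrombin provide the two independent thrombus-formation thresholds.
- **Protein C/S (RBu\*).** Thrombin–thrombomodulin activation of
  protein C, protein S cofactor binding, APC·PS inactivation of Va
  (solution and lipid-bound) and VIIIa, first-order APC clearance.
- **Phospholipid adsorption (Rad\*, and "d"-suffixed duplicates).**
  The species `PhosphoLipid` is the concentration of protein-binding
  sites on vesicles, at 333 lipid molecules per site. Xa, Va, IXa and
  XIa bind sites reversibly; duplicated reactions let lipid-bound
  factors react in their bound form (e.g. R9d, R28d). Prothrombinase
  holds one site (it assembles from solution Xa onto lipid-bound Va),
  so site bookkeeping is exactly conserved.
- **von Willebrand factor.** VIII circulates largely vWF-bound;
  thrombin activation releases VIIIa and regenerates free vWF.

Every parameter carries a provenance tag in the model-definition JSON:
`source-model` (from the cited sub-model literature),
`external-constant` (standard reference values: plasma concentrations,
measured drug Ki/kon, molecular weights), or `fitted-here` (calibrated
against clotting-test behaviour, below). The packaged model is
`src/coagsim/data/coagulation_model.json`; a TSV triple can be
exported for auditing. SBML export was considered and omitted — no
SBML library is a runtime dependency, and the JSON schema carries the
same information losslessly.

## Drug mechanisms

Four anticoagulants are kinetic mechanisms attached to the network
(species + reactions); warfarin is an initial-condition transform.

- **Rivaroxaban** (RBay1–RBay5): reversible binding to free,
  lipid-bound and prothrombinase-assembled Factor Xa, albumin binding,
  and slow ternary reactions with Xa–antithrombin. Measured constants:
  kon 1.7e7 l/(mol·s), Ki 0.4 nM for free Xa, unbound fraction ~5%.
  The prothrombinase-bound Ki is treated as a fitted constant (20 nM):
  Va-assembled, substrate-engaged Xa is protected, and this value
  places simulated PT ratios at clinical plasma levels (~1.5x at
  122 ug/l) in the range of published PT–concentration data.
- **DX-9065a** (RDx1–RDx5): same topology with Ki(Xa) 41 nM and
  moderate protein binding.
- **Melagatran** (RXi1–RXi4), the active metabolite administered as
  ximelagatran: reversible binding to thrombin (Ki 2 nM),
  meizothrombin and the thrombin–thrombomodulin complex.
- **Enoxaparin** (RHep1–RHep11): activation of antithrombin (ATIIIa)
  with catalytic turnover — every neutralisation of Xa, IIa, mIIa,
  IXa or XIa releases the heparin for another round. The
  anti-Xa constant is the largest of the set; the effective
  antithrombin affinity and the neutralisation constants are
  calibrated (tag `fitted-here`) so that PT and aPTT prolongation
  stays marginal within therapeutic concentrations (aPTT ~1.3x at the
  40 mg C_max), the behaviour reported for LMWH, while undiluted
  in-vivo levels remain strongly anticoagulant. Physically this folds
  in the minority of chains carrying the high-affinity
  pentasaccharide. Concentrations convert via 100 anti-Xa U/mg and an
  average molecular weight of 4500 g/mol.
- **Warfarin**: the initial concentrations of Factors II, VII (and
  VIIa), IX, X and proteins C and S are simultaneously reduced to the
  same fraction f of normal. `warfarin_fraction_for_inr` inverts the
  monotone INR(f) relation by bracketing root-finding (relative INR
  tolerance 1e-3); INR 3 corresponds to f ≈ 0.24, consistent with the
  clinical factor-activity range at that INR.

Protein binding uses a constant, dimensionless albumin pool species
(`Albumin_Factor` = 1 in plasma) that appears in binding rate laws but
has no stoichiometry; dilution scales it, which is what raises the
unbound drug fraction in diluted assays. Drug totals are
pre-partitioned to binding equilibrium at attach time so simulations
start without a binding transient.

## Virtual assays

All in-vitro assays share one recipe: multiply all plasma initials
(including drugs and the albumin pool) by the dilution factor, move 1%
of Factor V to Va, set the reagent phospholipid and trigger species at
final in-assay concentrations, integrate, and detect the clot.

- PT: dilution 1/3, TF 4 nM. aPTT: dilution 1/3, XIa 2.2 nM + XIIa
  50 nM. Thrombin generation: dilution 2/3, TF 5e-12 mol/l.
- Clotting time = first crossing of 100 nM fibrin, which is just over
  4% of the diluted 7 uM fibrinogen pool (100 nM / (7 uM/3) = 4.29%)
  — the onset of massive fibrinogen cleavage. The same criterion is
  used for PT and aPTT (no alternative is defined for aPTT).
- Trigger and reagent concentrations are final values set after
  dilution. The reagent phospholipid is 4 uM molecules (12 nM sites)
  for all three assays; the 1% Factor V preactivation is applied to
  the thrombin-generation scenario as well, for consistency across
  the in-vitro panel.
- INR = PT(therapy)/PT(control), ISI = 1; the control INR is 1 by
  construction.
- Assay horizon 600 s (3600 s for thrombin generation); "no clot
  within the horizon" is an explicit result for treated plasma but an
  error for the drug-free control.

The drug-free baselines come out at PT 53.6 s and aPTT 123 s — longer
than laboratory values (~12 s / ~35 s), as expected for a mass-action
network without reagent-specific surface catalysis; all reported
drug effects are ratios to these baselines, which the INR
normalisation makes comparable across reagents.

## Flow coupling and alpha_crit

The in-vivo open system adds, for every mobile species j, a transport
reaction with rate alpha·D_j·(c_j,blood − c_j) against an infinite
blood pool held at undiluted physiological concentrations (with
attached drugs at their binding equilibrium). D_j = 5e-7 cm²/s for all
species; alpha (1/cm²) lumps flow strength and geometry, so alpha·D is
a first-order exchange rate. Species bound to immobile tissue or
thrombus — TF, all TF complexes, and fibrin — are not transported.
alpha = 0 reproduces the closed model exactly.

Four trigger scenarios are used: TF 1e-11 / 1e-14 mol/l (extrinsic
strong/weak) and XIIa 1e-11 / 1e-14 mol/l (intrinsic strong/weak).
A coagulation event is a crossing of either of two thresholds within
3600 s: thrombin 2 nM (~0.1% of prothrombin) or fibrin 100 nM (the PT
criterion); both are configuration defaults, exposed in
`ClotDecision`. alpha_crit — the lowest alpha suppressing the event —
is found by bisection in log space with automatic bracket expansion,
to a relative bracket width of 1e-3 by default (2e-2 in the
benchmarking grid, where only orderings between therapies matter).
Absolute alpha_crit values have no experimental anchor and only
relative comparisons are interpreted.

## Numerical choices

- Integrator: BDF via `scipy.integrate.solve_ivp` with an analytic
  dense Jacobian; defaults rtol 1e-8, atol 1e-14 mol/l, overridable
  through `SimControls`. The network spans fM triggers to uM zymogens
  with near-diffusion-limited binding, so stiffness is assumed.
- Clot detection uses terminal integration events; crossing times are
  refined on the solver's dense interpolant with a bracketing root
  polish, with a 1e-7 relative threshold tolerance absorbing event
  interpolation round-off.
- Negative concentrations: values above −1e-12 mol/l are clipped to
  zero (integration round-off); anything more negative raises, to
  separate round-off from genuine model/parameter errors.
- Moiety conservation (prothrombin, fibrinogen, antithrombin, drug
  totals, phospholipid sites) holds to better than 1e-6 relative on
  closed-system runs; the check rejects weight vectors that are not
  left null-vectors of the stoichiometric matrix, so open (transport-
  coupled) models cannot be silently "checked".

## Benchmarking

Each dosing regimen (C_trough/C_mean/C_max from the packaged dosing
table, or warfarin at a target INR) is run against the four scenarios
for clotting time (static) and alpha_crit. Classification compares the
C_mean value against warfarin references: safe if the strong-extrinsic
clotting time does not exceed the INR-3 reference (alpha_crit: is not
below it); efficacious if the therapy reaches the INR-1.5 reference in
all three efficacy scenarios. Total daily dose aggregates "x OD" as x
mg/day and "x BD" as 2x mg/day; the therapeutic window is the span
from the lowest efficacious to the highest safe daily dose, with any
non-monotone flag pattern reported rather than masked.

## What the packaged inputs emulate, and limits

The packaged model definition and dosing table are the package's own
transcription of the coagulation literature: species
initials are standard plasma concentrations, the sub-network constants
are the cited source models' values, and drug constants mix measured
kinetics with the calibration described above. Consequences:

- Absolute clotting times and alpha_crit values are model-specific;
  ratios, orderings and dose-response shapes are meaningful.
- Emergent cross-drug comparisons depend on this parameterisation. The
  clot-time efficacy boundary computes to 20 mg/day rivaroxaban (the
  lowest dose matching warfarin INR 1.5 in all three efficacy
  scenarios). The safety boundary computes lower than reported
  clinically-anchored analyses (simulated rivaroxaban is relatively
  stronger than warfarin INR 3 under the strong extrinsic trigger),
  so the upper window edge lands at 10 mg/day rather than 40; the
  benchmark machinery reports whatever the parameterisation yields.
- Sensitivity checks on the free choices (thrombomodulin level,
  in-vivo phospholipid sites, burst- vs fibrin-based clot thresholds)
  do not change the rivaroxaban/warfarin ordering, so this is a
  parameter-provenance effect, not a threshold artefact.
- Passing tests demonstrate the engine's correctness (oracle-checked
  derivatives, conservation, closed-form limits, monotone
  dose-responses, reproducible bisection), not quantitative agreement
  with any specific clinical dataset.
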