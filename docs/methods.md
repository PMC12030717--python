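# Model and methods

## Scope

`tcbpbpk` simulates the disposition of CD3-engaging bispecific antibodies
(TCBs) and of T cells in a tumor-bearing mouse, down to the formation of
the trimeric CD3·TCB·HER2 immune synapse in the tumor interstitium. It
covers pharmacokinetics, biodistribution and target engagement only; no
downstream pharmacodynamics (T-cell activation, killing, cytokines) and no
species other than mouse.

## Body structure

The body is 14 compartments: venous and arterial plasma plus twelve organs
(lung, heart, spleen, lymph node, liver, kidney, gut, muscle, skin, bone,
tumor, rest-of-body), each split into vascular, interstitial and
intracellular fractions. Three structural values are fixed by the study
design this model reproduces: the tumor burden (240 mg at density 1 g/mL,
not scaled with body weight), the lumped-lymph-node volume
(4.04 mL per kg body weight) and the lymph-node sub-compartment fractions
(0.017 / 0.53 / 0.453, summing to exactly 1). All other organ volumes,
vascular/interstitial fractions, plasma flows and residual-blood fractions
are literature defaults from standard mouse PBPK tables, scaled linearly
from a 20 g reference animal; each organ row carries a `provenance` flag
(`printed-in-paper` vs `literature-default`). The rest-of-body flow closes
the cardiac-output balance exactly (plasma cardiac output 330 mL/h at
20 g).

A single lumped lymph node (not a chain) receives every organ's lymph and
drains to venous blood; this matches the aggregate way lymphoid tissue is
sampled in biodistribution studies.

## Antibody transport

Extravasation follows the two-pore formalism: large pores (radius
22.85 nm) and small pores (4.44 nm) carry fractions 0.3 / 0.7 of the organ
lymph flow. Steric partitioning gives, per pore class, a reflection
coefficient `σ = 1 − Φ(2−Φ)(1−λ/3)` and a Renkin diffusive hindrance
`Φ(1 − 2.104λ + 2.09λ³ − 0.95λ⁵)` with `Φ = (1−λ)²`, `λ` the solute/pore
radius ratio; solute flux is the Patlak convection–diffusion expression
`J(1−σ)·(C_p − C_i e^{−Pe})/(1 − e^{−Pe})`, `Pe = J(1−σ)/PS`, with the
Pe → 0 and Pe → ∞ limits evaluated in closed form. An IgG-sized solute
(hydrodynamic radius 5.34 nm) is fully excluded from the small pores, so
transport is essentially large-pore. The diffusive PS of each class is the
organ lymph flow times a class scale (large 2, small 10) times the
hindrance — an artifact-level closure chosen so that tissue uptake
equilibrates on the day–week scale typical of IgG. Lymphatic return
carries interstitial antibody at `L(1−σ_L)` with `σ_L = 0.2`. Organ lymph
flow defaults to 0.4% of plasma flow; the tumor uses 1.2% (leaky tumor
microvasculature), a calibrated default (see below).

FcRn is a lumped salvage model: vascular pools undergo endosomal uptake at
0.275 /h, of which a fraction `1/(1 + K_D/10600 nM)` is recycled to plasma
and the rest is catabolized into the organ's cumulative
residualized-label pool. At the wild-type endosomal affinity (500 nM)
about 95.5% is salvaged, giving the non-binding gD antibody a biexponential
blood profile with a terminal half-life near six days and plasma clearance
~0.016 mL/h — typical mouse IgG behavior. The catabolized pool has no
clearance over the simulation horizon, which is exactly the residualizing
(¹¹¹In-type) label assumption; the non-residualizing (¹²⁵I-type) signal
counts intact species only, with the catabolized amount booked as excreted
so whole-body %ID closes at 100%.

## T cells

Each organ has vascular and interstitial T-cell pools. Vascular pools
exchange with a central blood pool at the organ plasma flow; transmigration
is first-order with an organ-specific rate; egress is a global base rate
(0.3 /h) divided by an organ-specific retention factor and routes through
the lymph node before returning to blood. Exactly two parameters per organ
(transmigration, retention) are therefore calibratable, as in the staged
workflow. Activated cells transmigrate tenfold faster than naive cells
with identical retention; resting (endogenous) cells use 0.1× the
activated rate. Elimination of adoptively transferred activated cells is
first-order in the lung interstitium only; endogenous resting cells are
treated as a conserved pool of 2×10⁸ cells at its quasi-steady
distribution (no homeostatic source/sink), under which spleen and lymph
node are the dominant extravascular reservoirs. Lymph-node trafficking
parameters are tied to the spleen's. No proliferation is modeled.

Because the endogenous pool starts at its steady state and nothing in the
drug network moves cells, T-cell states are constant during TCB
simulations; they still live in the state vector so the same engine
simulates adoptive-transfer kinetics.

## Receptors and the synapse

CD3 capacity scales linearly with the local T-cell count (10⁵ receptors
per cell). Synthesis proportional to local cells feeds membrane and
internal pools in a 2:1 split while both pools decay at `k_deg,CD3`
(0.006 /h) and recycle with `k_rec = 0.5 /h`, `k_int = 0.5·k_rec`; this
keeps the membrane:internal ratio at exactly 2:1 and the total at
(cells × receptors/cell) at homeostasis. HER2 exists only in the tumor
interstitium: 2.4×10⁷ target cells × 4×10⁴ receptors/cell, zero-order
synthesis balancing first-order degradation (`k_deg,HER2 = 0.01 /h`), with
free and bound HER2 — including synapse-held HER2 — degrading at identical
rates.

The binding network is mass action in each sub-compartment:
`TCB + CD3 ⇌ TCB·CD3`, `TCB + HER2 ⇌ TCB·HER2`, and the two synapse
routes `TCB·CD3 + HER2 ⇌ synapse` and `TCB·HER2 + CD3 ⇌ synapse`, with
the avidity factor 0.01 multiplying both second-step dissociation rates
(equivalently, 100-fold avidity; the equilibrium constant product around
the thermodynamic cycle is path-independent by construction, and synapse
dissociation is effectively negligible at default parameters). Blood-borne
T cells carry vascular CD3, so blood dimers form; the synapse exists only
where HER2 does.

Internalization eliminates complexes: dimers at `k_int,dimer = 0.02 /h`,
HER2 dimers at `k_deg,HER2`, and the synapse at exactly
`k_int,dimer/3` (trogocytosis is slower because the target-cell receptor
must be stripped). The antibody of an eliminated complex joins the
catabolized-label pool; the receptor is consumed, with the
cell-proportional synthesis restoring the pool. This elimination routing
(rather than returning complexed CD3 to the recycling pool) is what lets
receptor pools deplete under sustained saturation; without it, local CD3
would inflate without bound while synthesis keeps running, and the
high-dose depression of the synapse peak could not occur. An engine-level
consequence worth stating: the bell shape in synapse Cmax versus dose
arises from tumor CD3 depletion during the long dimer-saturated phase of a
high dose (the pool settles near `k_deg,CD3/k_int,dimer` of baseline and
recovers only slowly, half-time ~115 h, before the drug concentration
finally sweeps down into the synapse-forming window), while at low doses
the pools are barely perturbed and the response is linear.

Complexes do not co-migrate with T cells between compartments (receptor
pools scale with local cells but drug bound to CD3 stays put); on the 72-h
calibration scale this is indistinguishable from explicit carriage, and it
keeps the drug network per-compartment.

## Molecule variants and calibrated defaults

Six molecules are predefined: gD (no binding arms), three one-armed CD3
variants of increasing affinity (gD-CD3L/H/VH) and two HER2 bispecifics
sharing the low/high CD3 arms (HER2-CD3L/H). All use `k_on = 0.36 /(nM·h)`
(10⁵ M⁻¹s⁻¹). The arm affinities and receptor-turnover defaults are not
printed in the source study, so they were calibrated — playing the role
the in-vivo fit played for the original authors — against the reported
system behaviors: CD3 K_D 120 / 0.15 / 0.115 nM (L / H / VH), HER2 K_D
10 nM (affinity-detuned HER2 arms are the norm for HER2 T-cell engagers).
Jointly with the turnover defaults above, these reproduce, in one
parameter set: (i) the 72-h blood ordering
gD > gD-CD3L > HER2-CD3L > gD-CD3H > gD-CD3VH ≥ HER2-CD3H on the
residualizing blood signal (blood was measured with the residualizing
label in the study design this mirrors — the signal includes label trapped
in blood cells after dimer internalization, which is what puts the
HER2-CD3H variant at the bottom); (ii) blood and tumor antibody AUC
proportional to dose (log–log slope within 2% of unity) over
10 µg – 100 mg; (iii) the monotone, plateauing synapse AUC and the slight
bell in synapse Cmax over 0.1 µg – 100 mg; and (iv) the monotone Tmax
delay above 300 µg. These behaviors are tightly coupled: the tumor sink
must be capacity-limited at the 0.5 mg/kg biodistribution dose (so both
HER2 variants lose a similar absolute amount to the tumor, separating them
from their gD counterparts without breaking dose-proportionality), and the
VH/H affinity step must be small enough that the tumor sink, not the CD3
arm, decides the bottom of the ordering.

Baseline tumor T-cell content is ~2.3×10⁶ cells (E–T ratio ≈ 0.095
against 2.4×10⁷ target cells); the E–T sweep multiplies the tumor
transmigration rate by 0.01–100, spanning E–T ≈ 0.002–2.

## Observables and synthetic data

Tissue signals are %ID/g at density 1 g/mL with additive residual-blood
correction `C_obs = C_tissue + rbf·C_blood`. The synthetic-data generator
reproduces the biodistribution study design: 0.5 mg/kg IV bolus, both
labels, three replicate animals per point, multiplicative mean-one
log-normal noise (default CV 20%), deterministic per seed. Its default
sampling (24 and 72 h) mirrors the sparse design of the emulated study;
the calibration experiments use a denser grid (2, 6, 24, 72, 168 h for
antibodies; 1 h – 2 weeks for T-cell kinetics) because binding and
turnover rates are kinetic quantities that two time points cannot pin
down — the in-vivo datasets the original workflow fit were themselves time
courses. What the generator does not emulate: inter-animal physiological
variability (noise is purely observational), assay backgrounds and limits
of quantification, and day-scale body-weight or tumor-growth drift.
Passing the recovery tests therefore shows the workflow is correct and the
design informative under the stated error model, not that real data of
this sparsity would identify the same parameters.

## Calibration

Three stages, later stages freezing earlier estimates: (1) spleen
transmigration and retention plus lung elimination against activated
T-cell kinetics; (2) FcRn affinity, dimer internalization and the
high-affinity CD3 `k_off` against gD and gD-CD3H, both labels; (3) HER2
turnover and `k_off` against the HER2 bispecifics. Objectives are
unweighted least squares on log observables (signals span decades; the
emulated workflow's weighting is unknown). Optimization is
Levenberg–Marquardt in log-parameter space (soft penalty at the bounds,
since LM is unconstrained) with seeded multi-start (default 8 starts,
perturbations up to 3-fold). Approximate standard errors come from the
Gauss–Newton Jacobian; parameters whose objective changes by less than 10%
over a 10-fold profile range are reported as non-identifiable rather than
as estimates.

## Numerics

Canonical units: nmol, nM, mL, h (amount-based states; bimolecular rate
constants converted once at assembly). All transport, trafficking,
turnover and internalization terms are precomputed into one constant
matrix; only the four binding reactions are evaluated per step, and the
analytic Jacobian (matrix + bilinear terms) is handed to scipy's BDF
solver (default rtol 1e-8; per-state atol scaled to the dose and the cell
pool). A 5000-h whole-body run takes well under a second. The pre-dose
state is the exact algebraic homeostasis (T-cell null-space distribution,
2:1 CD3 split, HER2 at synthesis/degradation balance), so a zero-dose run
holds steady to solver precision. T-cell-only simulations use the matrix
exponential of the linear generator (no solver tolerance at all).
AUC(0–∞) is trapezoidal plus a log-linear tail fitted on the last decade
of the time axis, with the extrapolated fraction flagged above 20% and a
non-decaying tail reported as AUC(0–t_end); synapse dose–response metrics
use the 5000-h integral directly because the synapse tail at very high
doses decays too slowly for a reliable extrapolation. Cmax/Tmax use a
parabolic refinement through the three points around the grid maximum so
Tmax does not quantize to the output grid. Negative states are clipped at
−1e-12 for reporting only.

## Known limitations

- Exact per-organ two-pore parameters, FcRn affinities and residual-blood
  fractions of the emulated mouse strain are not public; the shipped
  defaults are internally consistent literature values, provenance-flagged.
- The HER2 occupancy-by-synapse and occupancy-by-dimer time profiles at
  the 0.01 mg dose track each other with Pearson correlation ≈ 0.98, not
  higher: the HER2-engaged antibody in the tumor exceeds the tumor CD3
  pool at that dose, so free membrane CD3 drifts during the decay and the
  synapse:dimer ratio moves ~3-fold across the profile. Removing that
  drift (a much larger tumor CD3 pool) makes the tumor interstitium a deep
  CD3 trap and destroys the dose-proportionality of tumor exposure, so
  the present compromise is deliberate.
- No receptor clustering, membrane mechanics or synapse geometry; no shed
  antigen; no FcγR; no anti-drug antibodies; HER2 confined to the tumor.
- One molecule is simulated at a time (no competition between co-dosed
  variants), matching the emulated single-agent study arms.
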