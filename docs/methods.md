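# Methods

## Scientific problem

Photosynthesizing leaves release CO₂ in the light through processes other
than photorespiration — "respiration in the light", R_L.  Gas exchange can
measure its magnitude (the common-intersection/Laisk method) but not its
biochemical origin.  `leafflux` implements isotopically nonstationary ¹³C
metabolic flux analysis (INST-MFA) for this question: after a step switch
of the atmosphere to ¹³CO₂, the time courses of mass-isotopologue
distributions (MIDs) of central metabolic intermediates carry enough
information to estimate fluxes through the candidate CO₂-releasing
reactions — the glucose-6-phosphate/oxidative-pentose-phosphate shunt
(G6P → 6-phosphogluconate → pentose-P + CO₂), TCA-associated
decarboxylations (cytosolic/mitochondrial pyruvate dehydrogenase,
isocitrate dehydrogenase, α-ketoglutarate dehydrogenase, malic enzyme, net
of PEP-carboxylase refixation), and plastidic pyruvate decarboxylation
feeding fatty-acid synthesis.  Forced scenarios pin each candidate (or the
total) to the gas-exchange R_L and are compared by the variance-weighted
sum of squared residuals (SSR).

## Model and assumptions

* **Metabolic and isotopic model.**  Reactions with explicit carbon-atom
  transitions across plastid (`.p`), cytosol (`.c`, peroxisomal steps
  lumped in) and mitochondrion (`.m`).  Metabolic steady state is assumed
  throughout (N·v = 0 on balanced metabolites); only isotope labeling is
  transient.  Symmetric intermediates (succinate, fumarate — lumped here
  into one 4-carbon pool) carry 50/50 scrambled atom maps.
* **EMU decomposition.**  Measured fragments define target elementary
  metabolite units; backward traversal of the atom maps yields the minimal
  EMU closure, organized into blocks of increasing size.  Within a block
  the balance equations are linear with constant coefficients; condensation
  products enter as convolutions of strictly smaller EMUs.
* **Labeling kinetics.**  c·dx/dt = Σ v (x_src − x) per EMU, pools in
  µmol gFW⁻¹, fluxes in µmol gFW⁻¹ h⁻¹.  Reversible reactions use the
  net/exchange parameterization (forward = max(net,0) + exchange).
* **Measurement model.**  Simulations run in the fully corrected
  convention (M0 = 1 at t = 0); natural abundance (¹³C plus derivatization
  heteroatoms: H, N, O, Si, S at standard IUPAC abundances, configurable)
  is removed from raw spectra by solving raw = M·corrected, never added to
  simulations.  Fragments may mix moieties with fixed weights (sucrose
  m/z 361 = 0.54 fructosyl + 0.46 glucosyl; m/z 451 = 0.92/0.08; the
  in-house calibration, with the literature alternative 0.60/0.40, 0.95/0.05
  available by configuration).  Each metabolite may carry a metabolically
  inactive (principally vacuolar) dilution pool: observed =
  (1−d)·active + d·unlabeled.

## Numerical integration

The EMU cascade is integrated block by block on a shared geometric time
grid (60 points from 0.004 to 60 min by default).  Each block's coupling
matrix is eigendecomposed once and the state is advanced with the exact
exponential propagator plus trapezoidal (second-order) treatment of the
forcing (an ETD2 scheme); this is unconditionally stable, which matters
because C3-cycle pools turn over in seconds while the experiment lasts an
hour.  Exactly repeated eigenvalues (same-metabolite EMU families coupled
through one-way or scrambled cycles make some blocks defective at some
parameter points) are handled by a ±1e-6 relative diagonal split applied
with both signs and averaged, cancelling the perturbation's linear error
term; an adaptive BDF solve of the block is the last-resort fallback.  A
stacked adaptive `solve_ivp`
(LSODA, rtol 1e-8/atol 1e-10) path is retained as an independent
integration route; both are validated against a brute-force positional
isotopomer ODE (2ⁿ states per metabolite) on small toy networks to ≤1e-6.

The fixed default grid reproduces the adaptive reference to ~3e-3 in mole
fraction (second-order convergence, verified by grid doubling), far below
measurement noise.  The synthetic-data generator and the fitter share the
same grid, so a synthetic truth is exactly representable by the fitter and
noise-free self-consistency holds to machine precision.

## Flux fitting

Parameters searched by the optimizer: free net fluxes as coordinates in
the null space of the stoichiometric matrix (steady state holds exactly at
every iterate), exchange fluxes compactified as x = exch/(exch+1) ∈
[0, 0.999], and log pool sizes (bounds 10⁻³–20 µmol gFW⁻¹).  Dilution
fractions enter every MID residual linearly, so they are fitted by
variable projection: at each residual evaluation the optimal dilution
vector solves a small weighted linear system in closed form.  This removes
~25 nearly flat search directions while the dilutions still count as
estimated parameters in the degrees of freedom.

Residuals: every MID entry (measured − predicted)/sd with a 0.003
mole-fraction floor on the replicate-mean sd; boundary rates (net CO₂
assimilation at single-leaf gas-exchange precision, starch, sucrose,
hexose and malate accumulation) at their measured sd; and measured total
metabolite concentrations as residuals on log(active_pool/(1−dilution)) —
the total includes the vacuolar pool, and this coupling is what pins the
flux/pool/dilution compensation of slowly labeled, heavily diluted
metabolites.  Irreversibility, the rubisco v_o/v_c ∈ [0.2, 0.25] band, and
forced-scenario equalities enter as heavily weighted hinge/equality
residuals (scales 0.01 µmol gFW⁻¹ h⁻¹, 0.002 on the ratio, 0.2 % of the
forced target); penalties are excluded from the reported SSR and relaxed
5× during the global search phase so cold starts are not trapped against
constraint cliffs.  The ratio band is a penalty rather than a
v_o = r·v_c reparameterization because the fit runs in null-space
coordinates, where a flux ratio is not a box constraint; bound
satisfaction is asserted in the tests.

Optimization is staged multi-start trust-region least squares (`scipy`
TRF, finite-difference Jacobians with step 1e-6 — large enough to dominate
the integrator's path-switching noise).  Starts are stratified over the
candidate CO₂-source hypotheses (each start loads one source group,
cycling), with carboxylation solved from measured net assimilation and a
sampled oxygenation ratio, pools initialized from measured totals or
observed labeling half-times, and boundary-measured fluxes pinned.  Each
start gets a short screening budget; the best screened start of every
source hypothesis is refined (so no basin is dropped by a crude screening
cost) and the best candidates are polished with a capped iteration budget.
Forced scenarios warm-start from the unconstrained optimum via ramped
parameter continuation — the forced target is stepped from the optimum's
own value to the measured R_L, re-optimizing at each step — the same
protocol the reference software uses.  The fit is deterministic given the
seed.

Degrees of freedom are computed from the data — Σ per-fragment
T·(L−1) independent MID entries (rows sum to 1) plus boundary and pool
observations, minus fitted parameters — never hard-coded.  χ² acceptance
is two-sided at 95 %.

## Confidence intervals

* **Parameter continuation** (profile likelihood): the quantity is pinned
  and stepped away from its optimum, re-optimizing all other parameters;
  the 95 % bound is where the profile SSR crosses SSR_min + 3.84 (χ²₁),
  located by adaptive step halving; profiles flat to the search limit are
  flagged as open (structural non-identifiability).
* **Monte Carlo**: all measurements (MIDs and boundary rates) are
  resampled within their sd, refits warm-start from the unperturbed
  optimum, and the 2.5/97.5 percentiles form the interval.  Draws use
  seed-spawned substreams, so the estimate is reproducible and
  parallelizable by draw.  The reference analysis scale is 3,000 draws;
  the package default is 200 (configurable), and tests use 50–1,000.

Both routes are validated against the closed-form intervals of a linear
model (agreement within 1 % for continuation; within Monte-Carlo error for
the percentile CI) and against each other on a toy network.

## The synthetic study and its ground truth

No public MID tables exist for this system, so the generator defines the
study conditions: a reduced camelina source-leaf network (42 reactions,
34 balanced metabolites, 9 free net fluxes, 10 exchange fluxes — a
desk-scale counterpart of a published 72-free-flux model) with a
shunt-dominant truth: rubisco carboxylation 150 and oxygenation
30 µmol gFW⁻¹ h⁻¹ (v_o/v_c = 0.2), starch synthesis 9.5, sucrose synthesis
4.3, G6P/OPP shunt CO₂ 4.6, PEP carboxylation 1.1, cytosolic pyruvate
decarboxylation ≈0.7, isocitrate decarboxylation ≈0.7, negligible
α-ketoglutarate dehydrogenase/malic-enzyme flux and 0.1 through plastidic
pyruvate decarboxylation.  R_L(truth) = 5.2 µmol CO₂ gFW⁻¹ h⁻¹, 88 % from
the shunt and <10 % from TCA-associated reactions.  A vacuolar hexose and a
vacuolar malate accumulation sink close the daytime carbon balance (net
assimilation ≈130 µmol CO₂ gFW⁻¹ h⁻¹).

Pools and dilution fractions were chosen once to reproduce the published
labeling phenomenology: C3 intermediates 85–93 % enriched at 60 min with
sedoheptulose-7-phosphate highest (≈93 %), hexose phosphates slowed by
their cytosolic share, UDP-glucose ≈78 %, alanine ≈65 %, aspartate ≈32 %,
TCA intermediates and glutamate below 5 % (dilution 0.85–0.90 over small
active pools), and sucrose moiety M0 falling to a ≈40 % plateau after
30 min (active fraction 0.6).  Fragments that instruments cannot resolve
by compartment (PGA, triose-P, hexose-P, pyruvate) are modeled as fixed
mixtures of the plastidic and cytosolic pools in proportion to their
fixture concentrations.  The dataset also carries the study's other
measurements: boundary rates (net assimilation at 3 % single-leaf
precision; starch, sucrose, hexose and malate accumulation) and total
metabolite concentrations (internal-standard quantification, 20 %
log-normal error) for every detected metabolite — without the
concentration measurements the attribution of R_L is structurally
unidentifiable, because flux, pool size and dilution can compensate each
other for slowly labeled metabolites.

Sampling follows the experimental schedule (0, 0.5, 1, 2, 2.5, 3, 5, 7,
10, 15, 30, 60 min), 3 replicates, ~35 fragment ions from ~25 metabolites,
tracer purity 0.99.  Noise is Gaussian per replicate with a per-fragment sd
drawn once from 0.01–0.03 mole fraction, heteroscedastic (shrinking toward
the 0/1 rails with a 25 % baseline, as fraction noise does in practice)
and drawn on the simplex (zero row sum, since fractions are normalized
quantities).  It is deliberately NOT truncated at zero: corrected
instrument tables legitimately contain small negative fractions, and
truncation would bias the faint near-zero isotopologues of the TCA
intermediates upward by a large fraction of their uncertainty, which both
breaks the χ² calibration of the SSR and masquerades as TCA flux.
Reported sd is the generating sd of the replicate mean; the χ² calibration
property is asserted on a small toy fixture.

What the generator does **not** emulate: instrument-level effects (peak
shapes, mass interferences, MS scaling-factor drift), biological replicate
heterogeneity beyond i.i.d. noise, diurnal non-steady metabolism, and any
network reactions absent from the reduced model.  Passing the synthetic
recovery tests therefore demonstrates the estimator's correctness and
discrimination power under the stated conditions, not the biological
conclusions themselves.

## Problem sizes used in tests and the acceptance script

The scenario experiment runs on one seeded dataset: an unconstrained fit
with 20 multi-starts (6 in the test suite) under capped screen/refine/
polish iteration budgets, then forced-total and forced-TCA fits
warm-started from the unconstrained optimum by ramped continuation.  Coverage and method-agreement experiments for confidence intervals
run on a 2-carbon toy network (10 replicates; 60–1,000 Monte-Carlo draws),
where fits take milliseconds.  These sizes are the package's default
desk-scale choices; all are parameters of the respective functions.

## Known limitations

* The reduced network cannot reproduce the published SSR values (they
  depend on the unpublished full measurement set); scenario *ordering* and
  the unconstrained R_L *shares* are the reproduced quantities.
* Under the forced-total scenario, the attribution of the forced excess
  among the three sources is only weakly identified at this reduced scale:
  the optimum distributes roughly a third of the excess onto TCA-associated
  reactions at a statistically insignificant SSR cost (the relevant
  measured signals are a few percent against a 0.3 mol% uncertainty
  floor), whereas the full-scale study attributed ≈94 % to the shunt.
  Forcing *all* of R_L through a single wrong source is still decisively
  rejected (large SSR increase, concentrated on citrate for the TCA
  hypothesis), so the hypothesis-ranking conclusion is robust; the
  forced-total share percentage is not.
* Boundary-rate residuals and MID residuals are both weighted 1/sd²; the
  reference software's internal weighting may differ.
* MS scaling factors are available as optional per-fragment renormalization
  but default off (no published values).
* Dilution pools are static; a slowly exchanging vacuolar pool would need
  an explicit two-compartment extension.
* The G1P anomaly reported for this system is handled by exclusion (no G1P
  fragment in the fixture); an optional dilution pool on G1P would be the
  sensitivity check if such data were added.
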