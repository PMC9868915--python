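# Methods

`instmfa` implements isotopically non-stationary metabolic flux analysis
(INST-MFA) for compartmented central carbon metabolism, of the kind used to
phenotype heterotrophic plant cells: a bolus of [13C6]glucose is added to a
culture at metabolic (but not isotopic) steady state, intermediates are
sampled on a minutes-to-hours grid, and fluxes together with pool sizes are
estimated from the transient mass-isotopologue distributions (MIDs).

## Model

**Atom-transition network.** Metabolite pools carry a compartment tag and a
carbon count; reactions map every reactant carbon to a product carbon
(lowercase letters, one-to-one per side, so carbon is conserved by
construction — CO2 is explicit). Reversible reactions are a bidirectional
pair: forward flux `exchange + max(net, 0)`, backward `exchange +
max(-net, 0)`, with `exchange >= 0`. Rotationally symmetric molecules
(succinate, fumarate) are scrambled by averaging each atom map with its
reversal at weight 1/2; the same mechanism is available explicitly through
`(map1|map2)` alternates for lumped reactions. Net fluxes obey steady-state
mass balance on every balanced pool; the uptake reaction is fixed at 1.000 so
all fluxes are relative molar fluxes. QR factorization with column pivoting
of the stoichiometric matrix selects a well-conditioned set of free net
fluxes; the remainder are affine in them.

**Labelling dynamics.** The network is decomposed into elementary metabolite
units (EMUs) reachable backwards from the measured fragments. Each size-k EMU
block obeys `P dX/dt = A(v) X + B(v) Y` with `P` the pool sizes and `Y` the
inputs (substrate EMUs and Cauchy-product convolutions of smaller EMUs from
condensation reactions). Rather than solving levels sequentially against
interpolants, all levels are stacked into one block-triangular ODE and
integrated together with LSODA (rtol 1e-8, atol 1e-10 by default); this
avoids compounding interpolation error between levels, which matters because
the simulator is validated against an exhaustive isotopomer oracle at the
1e-8 level. Isotopic steady state is solved level-by-level as linear
systems. The initial condition is fully unlabelled; natural abundance is
handled on the measurement side, not in the simulator.

Substrate labelling is modelled as a position-exchangeable mixture (e.g. 60%
uniformly labelled + 40% unlabelled glucose), so a subset EMU of a source
pool carries the hypergeometric marginal of the molecular MID. Substrate
MIDs may be time-dependent callables, which is how delayed, first-order and
transiently diluted tracer-arrival scenarios enter.

**Observables.** Extraction mixes subcellular pools of the same metabolite
and dilutes some metabolites with metabolically inactive (vacuolar) material.
Each observable is a fitted convex combination of pool MIDs plus an
unlabelled fraction; the simplex is parameterized by stick-breaking logits.

## Measurement processing

Natural-abundance correction solves the nonnegative least-squares system
`C x = observed` with the carbon-only binomial convolution matrix
(p13 = 1.07% by default); forward-convolving the corrected MID reproduces the
observation to solver tolerance. Co-eluting species are separated by
constrained least squares over the mixing fraction and a simplex-projected
component; because any contaminant fraction up to the feasibility limit fits
an exact mixture, the convention is maximal contaminant removal (exact when
the clean component is dark in a contaminant channel). Fractional atom
enrichment is `sum_i a_i i / n`, optionally normalized by the substrate's
labelled fraction (values above 1.05 are flagged).

## Estimation

The objective is the variance-weighted SSR over all isotopologue
measurements (three replicate time-courses fitted simultaneously) plus
measured output fluxes. Measurement sigmas follow the mol% error model:
`sigma_min` below 0.5 mol%, `sigma_max` above 25 mol%, linear in between —
small isotopologues are thereby not assigned the proportionally huge errors a
purely relative model would give. One multiplicative MS normalisation factor
per (metabolite, time, replicate) MID is solved in closed form at every
residual evaluation and counted among the fitted parameters in the
degrees-of-freedom bookkeeping.

Minimization uses a damped least-squares trust-region method (scipy
`least_squares`, TRF) over free net fluxes (raw scale, bounded nonnegative
for irreversible reactions), log pool sizes, log exchange fluxes and mixing
logits; the log/logit transforms make the columns comparably scaled, and
`x_scale=1` is deliberately used because Jacobian-based rescaling stalls near
the optimum on this problem. Dependent irreversible fluxes are kept
nonnegative by a soft penalty residual (weight 1e3), active only outside the
feasible set. Multistart (default 32 random starts; net fluxes log-uniform
in [0.01, 2], exchange in [0.01, 10], pool sizes over three decades) guards
against local minima; the minimum-SSR start wins and per-start SSRs are
retained. A fit is accepted when the SSR lies inside the two-sided 95%
chi-square window for `n - p` degrees of freedom.

**Error calibration.** Synthetic noise drawn from the stated error model and
then clamped to [0, 1] and renormalized loses some variance (truncation at
hard zeros), so a fit weighted by the nominal sigmas lands below the
chi-square window — the analogue of real data whose replicate standard
deviations misstate the true uncertainty. As in the original workflow, the
error model is therefore calibrated: `(sigma_min, sigma_max)` pairs are
scanned in increasing magnitude and the smallest pair whose SSR enters the
window is adopted (rescoring the incumbent solution by default; full
refitting available).

## Uncertainty and significance

*Monte Carlo*: best-fit predictions are perturbed with Gaussian noise from
the error model (clamped and renormalized exactly like the generator), flux
measurements are perturbed by their sd, and the model is refitted from the
best-fit vector; 1000 rounds by default, failures recorded and never
silently dropped. Confidence intervals are ranked: sort, discard
`floor((1 - level/100)/2 * n)` from each end (83 values per side at 83.4%
with n = 1000).

*Continuation*: one parameter is stepped away from its optimum with all
others re-optimized (warm-started) until the profiled SSR crosses
`SSR_min + chi2_1(0.95)`; crossings are refined by root bracketing, flat
profiles yield unbounded sides, and any better solution found during the
scan replaces the incumbent and restarts the analysis. Pool sizes and
exchange fluxes are profiled in log space.

*Between-condition calls*: under equal variances (two-sided F test at 0.05)
non-overlap of the 83.4% intervals corresponds to P = 0.05; otherwise the
level is `[1 - 2 Phi(-1.96 sqrt(1 + rho^2)/(1 + rho))] x 100%` with rho the
ratio of ensemble standard deviations (the 1.96 constant is kept literal).

*Multivariate*: net biochemical fluxes only (pool sizes, exchange and pseudo
fluxes excluded; the fixed uptake dropped as zero-variance), autoscaled with
the sample-sd (n-1) convention. PCA is plain SVD with a
largest-loading-positive sign convention; PLS-DA is NIPALS PLS2 on the
centred class indicator with VIP importance, k-fold cross-validated accuracy
and a label-permutation null (defaults: 2 components, 5 folds, 100
permutations).

## Synthetic data generator

The generator defines the study conditions: 60% substrate enrichment, the
13-point sampling grid 0–270 min, 3 replicates, mol%-scaled Gaussian noise
(control 1.20–1.90 mol%, perturbed condition 1.45–2.15 mol%), clamped to
[0, 1] and renormalized (the truncation bias this introduces is what the
error calibration above absorbs). One master seed spawns independent
per-replicate, per-metabolite streams. Output fluxes of the ground truth are
exported as flux measurements with sd = max(0.02, 5%).

Two networks are bundled. `arabidopsis_core` transcribes the heterotrophic
central-metabolism map (cytosolic/plastidic glycolysis, oxidative and
non-oxidative PPP with transketolase/transaldolase carrier units, TCA cycle
with succinate/fumarate scrambling, PEP carboxylase and malic enzyme,
sucrose/starch/cell-wall and biomass outputs; 16 free net fluxes). Its atom
maps are textbook central-metabolism maps; published flux studies rarely
print theirs, so individual transitions may differ from any specific
original. `mini_heterotroph` is a deliberately small (2–3 carbon) lumped
network carrying the same flux motif — fixed uptake, unlabelled-store
dilution (0.162), pyruvate kinase (0.477) competing with the PEP-carboxylase
(0.685, exchange 0.2) / malic-enzyme (0.5) pair, decarboxylation feeding a
balanced CO2 pool that carboxylation refixes, and a slow malate pool (size
25, turnover ~20 min against ~0.3 min for PEP) observed with 25% inactive
dilution. Pool sizes were chosen once to spread turnover times from tens of
seconds to tens of minutes, mirroring the fast-glycolysis/slow-organic-acid
ordering of real labelling curves. All fitting-based tests and the
parameter-recovery analysis run on this reduced network so that a full
multistart fit plus Monte Carlo cycle completes in seconds on one CPU; the
problem sizes used there (8 starts, 100 Monte Carlo rounds, 20 repetitions;
200 rounds per condition in the two-condition scenario) are the package's
own desk-scale choices.

The perturbed ("oxidative") condition lowers pyruvate-kinase flux (0.477 →
0.173), raises the anaplerotic pair (0.685 → 0.940, 0.5 → 0.760) and lowers
the unlabelled-store input (0.162 → 0.113) — the flux signature of a mild
oxidative load, used by the bundled two-condition scenario.

What the generator does *not* emulate: correlated instrument drift,
retention-time artifacts, missing isotopologues, natural-abundance residuals
(data are generated post-correction), or biological replicate-to-replicate
flux variation. Passing tests therefore demonstrate correctness of the
estimator under its own assumptions, not robustness to violations real data
can show.

## Numerical choices and limitations

- Integrator tolerances rtol 1e-8 / atol 1e-10; tightened to 1e-10/1e-12
  where the isotopomer oracle is compared at 1e-8. Tiny negative MID entries
  from round-off (>-1e-9) are clamped to zero.
- The EMU-vs-isotopomer oracle is exponential in carbon count and guarded at
  4096 summed isotopomer states.
- Deconvolution is unidentifiable when the clean component has signal in
  every contaminant channel; only an upper bound on the contaminant fraction
  exists then, and the maximal-removal convention returns that bound.
- Exchange fluxes saturate: beyond the magnitude that effectively merges the
  two pools the profile is flat and the upper confidence bound unbounded —
  reported as infinity, not an error.
- Monte Carlo refits start from the best-fit vector (single start) for
  tractability; a full multistart per round would be safer against refit
  local minima and can be added where budget allows.
- CO2 is simulated as a balanced 1-carbon pool (produced by decarboxylations,
  consumed by carboxylation); a fixed-enrichment CO2 mode is available via
  `decompose(..., fixed_pools=["CO2"])`.
- The time grid is shared across metabolites and replicates within one
  fitted dataset; ragged designs are not supported.
- The ranked CI rule is mildly anti-conservative at small ensemble sizes:
  dropping floor(0.025 n) values per end at n = 100 keeps order statistics 3
  through 98, whose expected coverage is (98-3)/101 ~ 94.1% rather than 95%
  (at n = 1000 the effect is negligible). Empirical per-flux coverage over a
  handful of repetitions inherits binomial noise on top of that.
- Pool sizes estimated from MIDs alone can be far from their true values
  (weakly identified pools drift to bounds); they set the dynamics' time
  constants during fitting but should not be interpreted quantitatively.
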