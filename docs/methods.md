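# Methods

## The problem

Behavioural ecologists observe *samples* of social interactions — counts
of directed events (grooming bouts, support, aggression) between pairs
of animals — and want to infer the causes of the underlying interaction
network: does age change how much an individual engages? do kin interact
more? is an apparent kin effect an artefact of dominance rank? The
observed count `y[a,b]` is a noisy, unevenly sampled proxy for the true
rate `m[a,b]`, and the edges of a network are strongly dependent (shared
actors, reciprocity, kin blocks). srmkit treats both issues as one
modelling problem: a generative model of the network and of the sampling
process, fit in a Bayesian framework, validated by parameter recovery on
synthetic data before any real data are touched.

## The generative models

Four structural causal simulators produce directed dyadic count networks
with known ground truth. All share the observation layer

    m[a,b] = exp(intercept + gamma[a] + rho[b] + tau[a,b]),
    y[a,b] ~ Poisson(m[a,b]),

where `gamma` (giving) and `rho` (receiving) are individual latents and
`tau` a directed tie latent; the exponential link keeps rates positive
and makes all effects multiplicative on the outcome scale.

1. **Random features.** `gamma, rho ~ Normal(0, 0.5)` per individual,
   `tau ~ Normal(0, 0.5)` per directed dyad, intercept 0.2 (an average
   dyad exchanges `exp(0.2) ≈ 1.2` interactions per sampling period).
   Default 20 individuals in one closed group.
2. **Individual covariate.** `x ~ Normal(0, 1)` per individual enters
   the means of both `gamma` and `rho` with slope −0.7: e.g. older
   animals both give and receive less.
3. **Dyadic covariate + exposure.** 20 individuals in 11 kin groups (one
   matriline of 10, ten singletons). Binary kinship `Re = 1{K[a]=K[b]}`
   is z-standardized and enters the tie mean with slope 0.8 per SD;
   individual sampling effort `S[a] ~ Uniform(1, 2.5)` time units gives
   the dyadic exposure `S|a,b| = S[a]+S[b]`, entering as a `log S|a,b|`
   offset. Intercept −1.2, so an average non-kin dyad watched for 3.5
   time units yields `exp(−1.2 + log 3.5) ≈ 1.1` interactions.
4. **Confounded kinship.** Three closed groups of 10/15/20 individuals
   with at most 3/5/7 matrilines (labels drawn with replacement, so
   smaller groups are more related on average). Ranks are stratified by
   matriline — every member of a lower-labelled matriline outranks every
   member of a higher-labelled one; within-matriline order is random —
   and rescaled to (0,1] by ordinal position within the group (lower
   value = more dominant). The tie mean adds raw binary kinship (0.6)
   and an asymmetric rank term `0.8·(Ra[b]−Ra[a])` active only when the
   giver outranks the receiver. Because matrilines determine both
   kinship and rank proximity, the marginal kin/non-kin contrast does
   not identify the 0.6 kin effect: the backdoor through rank must be
   blocked by conditioning.

Every simulator is a pure function of its config and an integer seed
(independent sub-streams for each noise source), and stores the exact
latents and rates; `log m` equals the linear predictor to machine
precision. A `zero_noise` flag sets latent SDs to 0 so the deterministic
worked-example rates above can be reproduced exactly.

Design choices where the generative description was open: the group size
for models 1–2 (20, matching model 3, and small enough for fast
replicate fits); per-individual effort in model 4 as in model 3; kin
labels kept as drawn (no relabelling when fewer matrilines are
realised); rank ties broken by a dedicated sub-seed. The rank-difference
scale follows from the (0,1] rank convention, which reproduces the
worked arithmetic `exp(−1.2 + 0.8·0.7) ≈ 0.5` at a plausible rank gap.

## The estimators

The statistical counterpart is the multilevel Social Relations Model
(SRM): `log m[a,b] = D + G[a] + R[b] + T[a,b] + covariates + offset`,
with `(G[a], R[a])` bivariate normal (SDs `sG`, `sR`, generalized
reciprocity `cGR`) and `(T[a,b], T[b,a])` bivariate normal with a single
SD `sT` and dyadic reciprocity `cTT` — the exchangeable structure forced
by the arbitrariness of the labels a, b. Both layers are centred at zero
so `D`, `G` and `R` are jointly identifiable. Four variants mirror the
simulators: intercept-only; + individual covariate (slopes `bG`, `bR`);
+ offset and standardized relatedness (`bRe`); + offset, raw
relatedness, and the piecewise rank term (`bRa1` when the giver
outranks, `bRa2` otherwise). Dropping a term yields the deliberately
mis-specified comparators used to demonstrate leakage and confounding.
A continuous dyadic covariate is standardized exactly when the matching
simulator standardizes it (variant 3 yes, variant 4 no), with the same
`standardize()` (sample SD, ddof = 1) on both sides, so slope scales are
self-consistent.

**Priors** (all configurable via `prior_config`): Normal(0, 1) on the
intercept and every slope; Exponential(1) on `sG`, `sR`, `sT`; LKJ with
shape 2 on both 2×2 correlation matrices. These are weakly informative
on the log-rate scale of these problems (rates within a few fold of one
event per exposure unit) and regularise the correlations away from ±1.

## Inference

No probabilistic-programming backend is assumed: the package ships its
own No-U-Turn sampler operating on an analytic log posterior and
gradient. The model is non-centred (`G = sG·zG`, etc., with the 2×2
Cholesky factors written out), correlations are tanh-transformed and
SDs log-transformed with the Jacobians included, so the sampled space is
unconstrained and the hierarchical geometry is benign. Warmup uses dual
averaging of the step size (target acceptance 0.87) around doubling
mass-estimation windows (Welford variance with small-sample shrinkage
toward unit scale); trajectories stop at a U-turn or depth 9, and energy
errors beyond 1000 are counted as divergences, reported, never ignored.
The gradient has a compiled (numba) kernel checked against the pure
numpy reference implementation at every test run; finite-difference
tests pin both to ~1e-8 relative error.

Defaults follow the validation protocol: 4 chains × 2000 kept draws
after 1000 warmup iterations each (8000 posterior samples). Diagnostics
(`diagnose`) report rank-normalised split R-hat and bulk ESS for every
scalar parameter via arviz and fail a fit at R-hat > 1.01 or any
divergence. A `fixed_sds` option clamps the varying-effect SDs,
collapsing the model to a Poisson GLM in the fixed effects — a useful
degenerate check (the intercept posterior then sits at `log(mean y)`).

## Recovery studies and outcome-scale effects

`run_study` loops simulate → fit → diagnose over replicates (replicate
seeds `master_seed + i`), recording each fixed effect's posterior mean,
central 90% interval and whether it covers the generative value; failed
or non-converged replicates are flagged, never silently averaged. The CI
sampler profile (2 chains × 500 kept, 400 warmup) exists for desk-scale
runs; replicate-averaged posterior means at that profile agree with the
full profile well inside the ±0.15 recovery tolerance used in the tests,
because posterior-mean Monte Carlo error is a few hundredths at 1000
draws. Tests use 5 replicates; 15 reproduces the original protocol.

Because the link is exponential, a slope is not an effect size. From the
joint posterior the package computes, per draw: the dyad baseline
`psi[a,b] = D + G[a] + R[b] + T[a,b]`; conditional average treatment
effects `C_j = exp(psi_j + b) − exp(psi_j)` at chosen baseline levels
(default: 10/50/90% quantiles of the pooled psi draws); and
counterfactual rates `m0 = exp(D)`, `m1 = exp(D + b)` for an average
dyad with all varying effects and non-focal covariates at zero. The
identities `C_j = exp(psi_j)(e^b − 1)` and `m1/m0 = e^b` hold draw by
draw to machine precision and are asserted as such. Posterior predictive
checks replicate counts at thinned draws' rates and compare zero
fraction, maximum and mean count with the observed network.

## Known limitations

* The simulators emulate closed groups, stationary rates, Poisson
  observation and binary relatedness. Real data add overdispersion,
  temporal drift, measurement error in covariates (e.g. rank point
  estimates) and association-style sampling, none of which are modelled;
  passing recovery here validates the estimator under the stated
  generative assumptions, not beyond them.
* In the rank-confounded simulator, the rank-unadjusted estimator's
  relatedness slope is biased toward zero by roughly a third
  (posterior means ≈ 0.4 against a generative 0.6 at the default
  settings) — the direction and mechanism of the confound, though the
  collapse is partial at these effect scales: the rank term moves
  non-kin rates by at most `0.8 · |ΔRa| ≤ 0.8` on the log scale and
  kin/non-kin rank gaps differ by ~0.15 on the (0,1] rank scale.
* Reciprocity correlations `cGR`, `cTT` are statistical summaries;
  interpreting them as behavioural reciprocity requires the causal paths
  into them to be blocked, which only holds by construction in the
  simulators.
* The sampler is tuned for these SRM posteriors (hundreds of
  dimensions, smooth, non-centred). It is not a general-purpose
  replacement for a full PPL: no dense mass matrix, no per-parameter
  step-size control.
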