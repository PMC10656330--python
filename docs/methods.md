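# Methods

## The model family

Likert responses are modeled with IRTrees: each ordinal category is the
outcome of a short sequence of binary pseudo-decisions.  For a four-point
scale the tree has an *agreement* node (driven by the substantive trait
θ_p) followed by an *extreme* node; for a five-point scale a *moderate*
node (driven by midpoint response style κ_p) is visited first and choosing
the midpoint ends the tree, so the remaining pseudo-items are missing by
design.

The agreement node is a Rasch (or, optionally, loaded) logistic item,

    P(agree) = logistic(α_1i θ_p − β_1i).

The extreme node is multidimensional: both the trait and extreme response
style η_p load on it, and the trait term flips sign on the disagree branch
— conditional on agreeing, high trait levels push toward "strongly agree";
conditional on disagreeing, they push toward *moderate* disagreement,

    P(extreme | agree)    = logistic(α_i^(η) η_p + α_i^(θ) θ_p − β_2i),
    P(extreme | disagree) = logistic(α_i^(η) η_p − α_i^(θ) θ_p − β_2i),

with all loadings constrained nonnegative.

### Dynamic loadings

The package's central object is the loading trajectory

    α_i = (γ_1 − γ_I) (1 − ((i−1)/(I−1))^λ) + γ_I,

which moves a process's loading smoothly with item position i = 1..I.
γ_1 and γ_I are the loadings at the first and last item, the *slope*
γ_I − γ_1 is the total strategy change over the questionnaire, and λ
shapes the curve (linear at λ = 1; λ and 1/λ mirror the curvature, which
is why estimation restricts λ to [0.25, 4]).  The dynamic response
strategy model (DRSM) constrains the trait and ERS loadings of the
extreme node (and optionally the agreement-node trait loading) to such
trajectories.

The flexible variant (F-DRSM) adds item-level deviations:
α_i ~ Normal(μ_i, σ) around the trajectory mean μ_i, truncated at zero to
respect the nonnegativity constraint.  σ is estimated, so the data decide
how informative the trajectory is: σ → 0 recovers the DRSM, large σ
approaches the unconstrained 2PL model.

Six variants are available, differing only in the loading constraints:
ordinal (trait only, unit loadings), ERS (response style only), static
(two estimated constants), DRSM, F-DRSM, and 2PL (free item loadings).

## Priors and identification

* person parameters θ, η, κ: standard normal (this fixes the latent
  scale; for multidimensional questionnaires an option frees the SDs of
  all but the first trait dimension, with half-Cauchy(0, 5) priors);
* pseudo-item difficulties β_hi: hierarchical Normal(μ_β, σ_β) with
  Cauchy(0, 5) on μ_β and half-Cauchy(0, 5) on σ_β, one hierarchy shared
  across nodes;
* loadings, trajectory endpoints γ_1, γ_I, and the static constants:
  LogNormal(0, 2);
* trajectory shape λ: LogNormal(−0.5, 1) truncated to [0.25, 4].  This
  prior is deliberately informative near 1: when the slope is close to
  zero the shape is unidentified, and the prior keeps the sampler stable
  while pulling λ toward the linear case (visible in fits to static
  data);
* F-DRSM noise SD σ: half-Cauchy(0, 5).

## Estimation

Posterior sampling uses the No-U-Turn Sampler on an unconstrained
parameter vector, implemented in this package with analytic gradients
(the likelihood is a product of Bernoulli-logit node factors, so every
gradient is closed-form; a compiled kernel evaluates the person-by-item
pass, and an equivalent vectorized path serves as a correctness oracle in
the tests).  The sampler is multinomial NUTS with Stan-style windowed
warmup: dual-averaging step-size adaptation toward a 0.8 acceptance
target, and a diagonal mass matrix re-estimated in doubling windows.
Defaults are 4 chains, 500 warmup and 500 sampling iterations (a preset
with 1000 sampling iterations matches the empirical-application
settings), maximum tree depth 8, divergence threshold 1000.

Constraint transforms: nonnegative quantities are sampled on the log
scale (so the LogNormal priors act as normal densities on the sampled
coordinate); λ is a scaled logistic of an unconstrained coordinate on the
log scale, with the transform Jacobian included; the F-DRSM item loadings
are non-centered — α_i = max(0, μ_i + σ z_i) with z_i ~ Normal(0, 1) —
which mirrors the generator's truncation at zero exactly and avoids the
funnel between σ and the deviations (a log-scale centered
parameterization was tried first and mixed noticeably worse).

Point estimates are EAPs (posterior means); intervals are equal-tailed
quantile intervals.  Convergence is flagged, not silently ignored: a fit
whose maximum split R-hat (computed by ArviZ) exceeds 1.05 carries
`converged_ = False` and raises a warning.  The replication harness
records, excludes, and counts such fits.

## Model comparison and post-hoc analysis

Out-of-sample fit is PSIS-LOO (ArviZ) on the person-item pointwise log
likelihood of the *ordinal* response — the finest observable unit — and
is reported on the information-criterion scale (−2·elpd) so smaller is
better; elpd and Pareto-k diagnostics are kept alongside.  Model
selection uses the strict minimum without standard-error banding; ties go
to the first model listed and are flagged.

The 2PL model has no trajectory of its own, so a position trajectory is
fitted through its free loading estimates post hoc by bounded nonlinear
least squares, multi-started over 8 log-spaced shape values in [0.25, 4]
to avoid local minima.  For a flat loading profile the shape is
unidentified and the fit says so (`shape_identified = False`) rather than
reporting an arbitrary λ.

## The simulator

The generator reproduces the two simulation designs: person parameters
and pseudo-item difficulties i.i.d. standard normal and mutually
uncorrelated, loadings set by the variant (unit/zero, constants 0.3/0.7
or 0.7/0.3, trajectories drawn from the printed grid (0.8; 0.2), (0.7;
0.3), (0.6; 0.4), (0.5; 0.5) with mirrored ERS trajectories, λ ∈ {2,
0.5}), and pseudo-item responses sampled as independent Bernoulli draws
from the model-implied branch probabilities, then reassembled into
categories through the tree map.  The second design centres all three
trajectories at 0.5, varies the absolute slope over {0, 0.2, 0.4, 0.6},
adds loading noise of SD 0.1 or 0.2, and gives the agreement node its own
trajectory.  The second design does not restate a shape value; the
package reuses λ = 2 (with λ = 0.5 available through the grid switch),
since all other settings carry over from the first design.

Seed policy: replication r of a condition draws from the counter-based
stream `default_rng([base_seed, r])`, so any replication is reproducible
in isolation.  Generated loadings below zero are truncated to zero, the
same rule the estimator's non-centered parameterization applies.

What the generator deliberately does not emulate: correlated traits and
response styles, person-specific item order, careless or mixed response
states, non-monotone trajectories, and item-content effects.  Passing
tests therefore show that the estimators recover the models' own
data-generating processes at the stated sizes — not that real
questionnaire data satisfy these assumptions.

## Problem sizes in the test suite and acceptance script

Desk-scale reproductions keep each run on one CPU:

* acceptance script: 5 replications per condition at N=500, I=20, 4
  chains, 500/500 iterations — the reduced sample-size arm of the first
  study's grid;
* slope-recovery and specificity tests: 5 replications at N=400, I=16
  and N=220, I=12 with shorter chains (below roughly N=400, I=16 the
  ERS trajectory's posterior becomes strongly prior-shrunk, so the
  recovery check is not meaningful at smaller sizes);
* model-selection trend: 10 replications × 3 change sizes × 2 models at
  N=200, I=12;
* noisy-trajectory comparison: 5 replications × 2 noise SDs of F-DRSM
  vs. 2PL at N=250, I=16.

At these sizes the qualitative results are stable but individual numbers
move by more than at the full design (100 replications at up to N=1000,
I=40); tolerances in the tests are therefore Monte-Carlo standard errors
across replications rather than printed-table digits.

## Numerical choices and edge cases

* Category probabilities are products of logistic node factors; the
  likelihood is accumulated in log space cell-wise, so branch-probability
  underflow cannot produce zero products.
* Missing ordinal responses are allowed and dropped cell-wise from the
  likelihood; missing-by-design pseudo-items contribute nothing.
* Inverted items flip the sign of every trait term of that item
  (agreement node and both extreme branches); loadings remain
  nonnegative and keep their "strength of involvement" reading.
* Trajectory groups (e.g. item wording) give each group its own
  (γ_1, γ_I, λ) per process.
* The compiled likelihood kernel runs without fast-math reassociation so
  results are bit-reproducible across machines with the same library
  stack.
* `posthoc_trajectory_fit` requires ≥3 finite loadings; ties across
  multi-starts resolve to the first best solution.

## Known limitations

* Trajectories are group-level: everyone shares one strategy-change
  curve per process (and per item group), so individual differences in
  dynamics are not modeled.
* Only monotone trajectories are supported; U-shaped or change-point
  strategies are out of scope.
* The F-DRSM's truncation at zero makes the noise distribution censored
  rather than exactly normal near zero; with trajectory means well above
  zero (the simulated designs) the difference is negligible.
* Cross-loadings are not supported: each item measures exactly one trait
  dimension.
* MCMC only; no marginal maximum likelihood or variational path.
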