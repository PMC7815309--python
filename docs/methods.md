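# Methods

## The task environment

The synthetic task reproduces the statistical structure of a three-armed
bandit paradigm designed to dissociate exploration heuristics.  Each trial
displays three bandits drawn from four generative types that differ in mean
reward and in the amount of prior information shown before the first
choice:

| type             | initial samples | generative mean                          |
|------------------|-----------------|------------------------------------------|
| certain-standard | 3               | μ_cs ~ N(5.5, 1.4²)                      |
| standard         | 1               | μ_s = μ_cs ± {1, 2}, 4 equiprobable cases |
| novel            | 0               | μ_n = μ_cs or μ_s ± {1, 2}, 8 cases       |
| low-value        | 1               | μ_l = min(μ_cs, μ_s, μ_n) − 1            |

Rewards are Normal(μ, S²) with sampling variance S² = 0.8, rounded to the
nearest integer, and truncated to the closed interval [2, 10] — nine
possible values.  The generator samples integers directly from the
normal's mass over each rounding cell renormalised over the interval,
which is exactly the law of "round, exclude out-of-interval values,
redraw" without the non-termination risk of literal rejection; the test
suite checks the equivalence against a literal rejection sampler.  The
printed "S = 0.8" is interpreted as the *variance* (τ_samp = 1/0.8 = 1.25),
the reading consistent with τ_samp = 1/S²; both are configurable.

The low bandit's shown sample must be strictly smaller than every other
displayed initial sample (so it is identifiable as the low-value option);
all displayed samples are redrawn jointly until this holds.  In the rare
tail where μ_cs is drawn so low that every sampled bandit sits at the
reward floor of 2, strict ordering is impossible, so after every 1,000
failed redraws the trial's means are resampled as well.  μ_l itself may
fall below 2; its rewards are still truncated to [2, 10].

Each of the four three-bandit combinations contributes 25 unique trials
(100 total).  Every unique trial is duplicated — same types, generative
means and realised initial samples; positions and colours reshuffled — to
measure choice consistency, and each duplicated pair is played in both a
short (1 draw) and a long (6 draw) horizon: 400 trials, randomly assigned
to 4 blocks.  Whether duplicates may share a block is not constrained.
Per-trial RNG substreams are spawned from the task seed, so unique trial k
of a combination is invariant to `trials_per_combination` and generation is
bit-reproducible.

## Belief updating

Agents hold Gaussian beliefs N(Q, 1/τ) per displayed bandit, initialised at
the prior (Q0, σ0²) and updated conjugately by each observed sample m:

    Q ← (τ·Q + τ_samp·m) / (τ + τ_samp),   τ ← τ + τ_samp

— the stationary-bandit Kalman filter.  After n samples
τ = 1/σ0² + n·τ_samp exactly, and the posterior mean is a precision-weighted
convex combination of Q0 and the sample mean.  The novel bandit receives no
updates before the first draw.  τ_samp is fixed at the generative 1.25
rather than fitted; letting subjects' assumed sampling noise vary is
conceivable but would trade off against σ0 and is left out.

## Choice rules

Twelve models: three bases crossed with two binary heuristic extensions
(c_vf for the ε-greedy component, c_n for the novelty bonus), named
`<base>[+vf][+nov]`.

**UCB**: V_i = Q_i + γσ_i + c_n·η·δ(i = novel), choice by softmax with
inverse temperature β (max-shifted for numerical stability).  γ multiplies
the posterior SD, as printed.

**Thompson (probability of maximum utility)**: V_i = Q_i + c_n·η·δ(i=novel);
a notional sample x_i ~ N(V_i, σ_i²) is drawn per bandit and the largest
wins.  With three bandits the choice probability of bandit i is the
positive-orthant probability of the bivariate normal of pairwise
differences u = (x_i − x_j, x_i − x_k), with mean (V_i − V_j, V_i − V_k)
and covariance [[σ_i²+σ_j², σ_i²], [σ_i², σ_i²+σ_k²]] — the difference
matrix is applied to the *variances* (a covariance matrix requires σ², and
the sampling statement is x ~ N(V, σ²)).  The orthant probability is
evaluated analytically through Owen's T function
(`scipy.special.owens_t`), vectorised over trials, to near machine
precision; the tests check it against `scipy.stats.multivariate_normal`
and against 10⁶-draw Monte-Carlo argmax frequencies.  The three per-bandit
probabilities are clipped at 0 and renormalised to absorb rounding at the
1e-15 level.

**Hybrid**: w·P_UCB + (1 − w)·P_Thompson, both components computed with
c_vf = 0.

**Value-free extension**: P ← P·(1 − ε) + ε/3, applied after the base rule,
so every displayed bandit keeps probability ≥ ε/3.  ε is bounded by 0.5
during fitting and may extend to 1 in simulation (ε = 1 is the uniform
policy used as the chance baseline).

**Novelty extension**: η is added to the novel-type bandit's value.  During
within-trial simulation of long-horizon episodes the bonus applies only
while the bandit still has no observed samples — novelty is read as
"no information yet", so an agent's own draw de-novelises it.  Fitting uses
first draws only, where the two readings coincide.

## Parameters

All parameters except the prior mean Q0 and the hybrid weight w may differ
between horizons (short = 1 draw, long = 6), since they express exploration
pressures that the horizon modulates; Q0 and w are beliefs/arbitration and
are shared.  The winning model `thompson+vf+nov` therefore has 7 free
parameters: Q0, and per-horizon σ0, ε, η.

Fitting bounds: σ0 ∈ [0.01, 6], Q0 ∈ [1, 10], ε ∈ [0, 0.5], η ∈ [0, 5].
β and γ bounds are not dictated by the source analyses; the defaults are
β ∈ (0, 50] and γ ∈ [−5, 20] (mildly negative γ lets the data reject
uncertainty seeking), w ∈ [0, 1]; all configurable.

## Estimation

Per subject, by MAP: the objective is the negative log likelihood of the
observed *first draws* (long-horizon draws 2–6 are simulation-only) minus
the log prior of Q0 ~ N(5, 2) (SD), the prior approximating the generative
mean distribution.  The other parameters carry uniform priors over their
bounds, so their estimation is equivalent to MLE.  Choice probabilities
are floored at 1e-10 inside logs, since ε-free models can assign
essentially zero to an observed choice.  Optimisation is bounded L-BFGS-B
from 8 (configurable) uniform-random interior starts (jittered 1e-3 off the
bounds), keeping the best; determinism follows from the fit seed.  The
optimiser choice is a contract (bounded local quasi-Newton search with
configurable tolerances), not a re-implementation of any particular
solver.

## Model comparison

10-fold cross-validation per subject over the 400 first draws.  Folds are a
simple random partition by default; horizon-stratified and
duplicate-grouped folding (keeping a trial and its duplicate in one fold)
are available, since the source description does not say how duplicates
were assigned.  Training-fold fits use MLE with multi-start; the held-out
score is the mean predicted probability of the observed choices, in
percent, averaged over folds.  A `uniform` baseline (always 1/3) is scored
without fitting at exactly 100/3.  Per-subject best-model ties break toward
fewer free parameters.

## Validation pipelines

*Signature experiments.*  200 agents of the winning model play 200 trials
of a single (long) horizon condition per regime.  Value-free: ε ∈ {0, 0.2}
with (σ0 = 1.312, η = 2.625, Q0 = 3.2) fixed; novelty: η ∈ {0, 2} with
(σ0 = 1.312, ε = 0.1, Q0 = 3.2) fixed.  The high-ε regime raises
low-value-bandit frequency and lowers consistency; the high-η regime raises
novel-bandit frequency.  Each agent receives a freshly generated task.

*Parameter recovery.*  A Cartesian grid of equally spread values per free
parameter (study scale: 4 values ⇒ 4⁷ agents; ranges σ0 ∈ [0.5, 2.5],
Q0 ∈ [1, 6], ε ∈ [0, 0.5], η ∈ [0, 5]); one agent is simulated per grid
point, refitted by MAP, and generative vs recovered values are correlated
(Pearson) per parameter, with recovered-value spread per generative level
also reported.  "One new trial for each" is read as one freshly generated
*task set* per agent (7 parameters cannot be identified from a single
trial); a shared-task mode is available behind a flag.

*Model validation.*  Behaviour is re-simulated from (fitted) parameters —
default 4,000 trials per agent — and the behavioural metrics of simulated
and observed data are tabulated side by side.

## Behavioural metrics

Selection frequency per bandit type is a percentage of *all* first-draw
trials in a horizon (each type is absent on a quarter of trials, so 75% is
the ceiling).  Consistency is the percentage of duplicated pairs — matched
by bandit type, because positions are reshuffled — with the same first
choice; each pair counts once.  The expected value of the first choice is
the mean of the chosen bandit's shown initial samples, excluding
novel-bandit choices (which show none); information seeking is the mean
number of initial samples of the chosen bandit, novel counted as 0.  The
high-value option is defined only on trials displaying both the
certain-standard and the standard bandit as the displayed bandit with the
highest initial-sample mean; ties leave it undefined and such trials drop
out of the high-value frequency.  Group-level inferential statistics
(ANOVAs with covariates, effect sizes) are deliberately not reimplemented —
the metrics module emits tidy per-subject tables for standard statistics
software.

## Problem sizes and numerical choices in the shipped checks

The test suite exercises the pipelines at sizes chosen for a desk-scale
run: signature experiments at the full 200 agents × 200 trials; parameter
recovery at 2 values per parameter (128 agents, 400 trials each, MAP with
8 starts) plus an asymptotic-bias spot check at 10,000 trials on 3 grid
points; model recovery at 20 agents × 400 trials, all 12 models under
10-fold CV with 2-start, 60-iteration MLE training fits.  Monte-Carlo
oracle comparisons use 3-SE tolerances at their stated draw counts, with a
4-SE cap when 150 comparisons are made simultaneously.  The full 4⁷
recovery grid remains available through
`generate_recovery_grid(n_values_per_param=4)`.

## What the synthetic data does and does not show

The generator reproduces the environment's statistics (generative means,
reward law, duplication, horizons) and the agents are the package's own
models, so passing tests demonstrate *internal* consistency: the estimator
recovers the parameters of data the models generated, and model comparison
re-identifies the generating model.  They cannot demonstrate that human
subjects are described by these models, nor reproduce group-level effects
that depend on real subject data (e.g. held-out accuracies of real
choices, drug effects); those quantities are out of scope here.

## Known limitations

* Thompson sampling is implemented for exactly three displayed bandits
  (the task's format); the orthant computation would need generalising for
  k ≠ 3.
* Deterministic (large-β) agents leave the likelihood flat over parameter
  plateaus, capping held-out accuracy below 100% even for the generating
  model; exact posterior-mean ties are resolved by coin flips.
* η and σ0 recover less sharply than ε at single-subject trial counts —
  visible as spread in the recovery report — because they act only through
  the novel bandit and the prior weight.
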