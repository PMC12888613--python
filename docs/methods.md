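# Methods

This note documents the models, the fitting and comparison machinery, the
synthetic study generator, and the numerical choices behind `traitlearn`.
It is the package's own account of its science; every number quoted here is
computed by the test suite or the analysis drivers, not asserted by hand.

## The task being modeled

A participant learns about six target people ("profiles") by predicting, on
a 1–8 scale, how strongly each of 40 personality trait words applies to the
target, receiving the target's actual self-rating as feedback after every
prediction. The 40 traits are balanced over the Big Five factors (7–9 per
factor) and over social valence (20 positive, 20 negative words). Each
profile block presents all 40 traits once, in randomized order; six blocks
give 240 trials. Three profiles follow a borderline-personality-like (BPD)
rating pattern and three a control-like pattern, presented in the fixed
class order CON, BPD, CON, BPD, BPD, CON. Participants also rate themselves
on the same 40 traits.

All model-internal quantities live on the **favorability scale**: ratings of
negative-valence traits are reverse-coded, `r -> (scale_min + scale_max) - r
= 9 - r`, so that "higher = more socially favorable" holds uniformly. This
matters because a factor-level or similarity-weighted expectation is
incoherent over mixed-valence raw ratings (an "anxious = 7" and a
"calm = 7" pull a shared Neuroticism expectation in opposite directions).
Raw-scale values are restored at the I/O boundary; the absolute prediction
error `PE_t = |F_t - P_t|` is invariant under joint reverse coding, so it
can be computed on either scale.

## The model family

Eight base models, three generative ideas:

**No-learning** (2 models). The response on every trial is a fixed reference
point plus Gaussian noise: the population-average rating of that trait
(`none_popRP`) or the participant's own self-rating (`none_selfRP`).
Nothing updates. Free parameter: sigma.

**Coarse granularity** (3 models). One expectation per Big Five factor,
initialized at V0 and updated by a delta rule toward the feedback on the
observed trait's factor:

    V_f  <-  V_f + alpha * (F_t - V_f)

Variants without a reference point predict `V_f`; variants with one predict
the convex mixture `w * RP + (1 - w) * V_f` (population or self RP). Free
parameters: alpha, sigma, and w where applicable.

**Fine granularity** (3 models). One expectation per trait; feedback on
trait j generalizes to every trait i through a similarity weight `s(i, j)`:

    V_i  <-  V_i + alpha * s(i, j) * (F_t - V_j)

with the same reference-point variants. The similarity matrix is the
trait-trait Pearson correlation computed from a reference rating table on
the favorability scale (see below). Block similarity (1 within factor, 0
across) makes the fine model reproduce the coarse model exactly when V0 is
constant within factors — the test suite asserts this equivalence to 1e-10,
which pins both update rules against each other.

**Extended V0 variants** (6 models, `*_v0`). Instead of fixing the initial
expectation at the scale midpoint (4.5), the per-trait V0 vector is
estimated, hierarchically shrunk toward a scalar condition-level mean. V0 is
condition-level (shared by the condition's participants); a per-participant
per-trait V0 would add 40 parameters per participant and is not
identifiable at one observation per trait per block.

Design choices worth stating explicitly:

* **Likelihood.** Responses are modeled as a plain (untruncated) Gaussian
  around the predicted rating, `P_t ~ Normal(mu_t, sigma)`. The comparison
  metric downstream is squared error, which is the matching loss. Simulated
  responses are rounded to integers and clipped to [1, 8]; the likelihood
  ignores rounding (it adds ~1/12 to the effective noise variance, visible
  in recovered sigmas, and is noted where tests check noise recovery).
* **Reference points enter at prediction time** as a convex mixture with
  weight w, not as an initialization of V0. An initialization-only reading
  is representable through the extended V0 models.
* **Teacher forcing.** States update on the observed feedback — also for
  trials excluded from the likelihood (participants saw that feedback; only
  their response is discounted).
* **State resets at profile boundaries.** Each profile is a new person, so
  V restarts from V0 at every block start. This also makes the
  log-likelihood exactly additive over blocks.
* **Signed generalization** is allowed (anti-correlated traits update in
  opposite directions); a flag clips similarity at zero if wanted.

## Hierarchical fitting

Each condition (participant group x profile type) is fitted independently.
Participant parameters are non-centered draws from condition-level
distributions on unconstrained scales:

    logit(alpha_s) = mu_alpha + tau_alpha * z_s      z_s ~ Normal(0, 1)
    logit(w_s)     = mu_w     + tau_w     * z_s
    log(sigma_s)   = mu_sigma + tau_sigma * z_s

with priors `mu ~ Normal(0, 1)` and `tau ~ HalfNormal(1)` — weakly
informative and scale-aware (the implied prior median learning rate is 0.5
with mass over the whole unit interval). For extended models,
`v0_i = vbar + s_v * u_i`, `vbar ~ Normal(4.5, 2)` in rating units,
`s_v ~ HalfNormal(1)`, `u_i ~ Normal(0, 1)`. Reported condition-level
parameters are on the natural scale; `mu_alpha` is the population *median*
learning rate `expit(mu)`.

**Sampler.** The posterior is sampled with the emcee affine-invariant
ensemble sampler (differential-evolution moves, 80% DE / 20% snooker) over
a vectorized log-posterior, initialized at a pooled point estimate with
dispersed non-centered deviates. Defaults: max(64, 2*dim+2) walkers, 3000
warmup and 2000 retained steps. Convergence is summarized by arviz rhat and
bulk ESS with each walker treated as a chain; this is a heuristic for
ensemble samplers (walkers are not independent chains) and is deliberately
conservative — fits that miss the thresholds (rhat < 1.01, ESS >= 400) are
returned with a warning flag, never silently accepted. Ensemble samplers
have no divergent transitions; the divergence fraction is recorded as 0 to
keep the diagnostic contract uniform. Reduced budgets (800/600) give
posterior intervals indistinguishable from long runs on the recovery
problems in the test suite while tripping the conservative flags; the
recovery tests therefore assert coverage and correlation, not the flags.

**Likelihood caching.** Two structural facts make sampling cheap for the
non-V0 models: the latent-state recursion depends only on alpha (teacher
forcing), and the residual is affine in w, so the summed squared error
decomposes as `SSE(alpha, w) = A(alpha) - 2 w B(alpha) + w^2 C(alpha)`.
A, B, C are tabulated per subject on a 257-point alpha grid and
interpolated with cubic splines; sigma enters in closed form. The cached
and direct paths agree to ~1e-8 in log-likelihood (tested); estimated-V0
models use the direct vectorized path.

**Contrasts.** Group-level comparisons sample the posterior difference
distribution of condition-level means and report its mean and 95% shortest
probability interval (SPI) — the narrowest contiguous interval containing
95% of the sorted draws; a difference is "credible" when the SPI excludes
zero. Draw counts are equalized by even-index subsampling of the longer
vector.

**Single-subject fits** (`fit_map_subject`) maximize the sequence
likelihood plus weak priors (logit-scale Normal(0, 1.5) on alpha and w,
log-scale Normal(0, 1) on sigma) with seeded multi-start L-BFGS; they serve
as a fast fallback and sampler initialization, not as the inference path.

## Model comparison

Leave-one-group-out cross-validation, where a "group" is one participant's
full trial set: fit on the remaining participants, predict the held-out
participant teacher-forced with condition-level point estimates (posterior
means in accuracy mode; a pooled penalized-ML estimate in fast mode), and
score the mean squared error over the held-out valid trials. Self-RP models
use the held-out participant's own self-ratings — those are data available
for a new participant, not fitted parameters. The naive baseline predicts
the grand mean of the training participants' ratings for every held-out
trial.

Fast mode exploits the additivity of per-subject SSE components: one alpha
grid pass per model serves all folds (each fold's pooled objective is the
total minus the held-out subject), with the optimal w in closed form per
grid point and, for extended models, a coarse outer grid over the V0 level.

Two models are credibly different when |ΔMSE| exceeds twice the standard
error of the paired participant-level score differences (`sd(d)/sqrt(n)`),
without multiplicity correction. Rankings sort by overall MSE; ties break
by fewer free parameters, then model id. The "best set" is the best model
plus every model not credibly different from it.

## The synthetic study generator

The generator emulates the statistical structure the analysis assumes, with
every stochastic step driven by participant-indexed substreams of one
master seed:

* **Class trait distributions.** Per-trait favorability means center on
  6.22 for the control-like class and 0.77 units lower for the BPD-like
  class — the default group effect in rating units — with a shared
  per-trait jitter (SD 0.6) and a per-trait rating SD of 1.3. The 0.77
  group gap propagates to cohort self-ratings (and hence to self-RP
  behavior and the favorability summaries).
* **Profiles.** Three per class, drawn around the class means with the SD
  shrunk to 0.6 of the class SD — profiles are *typical* group members, as
  screened stimuli are — rounded, clipped, and accepted only if at most six
  traits deviate from the class mean by more than 1 SD (bounded redraws).
* **Reference table and similarity.** A synthetic population (60 people per
  class) with latent Big Five factor scores (loading 1.0, unique noise SD
  0.9) provides the within-factor correlation structure; the empirical
  similarity matrix and the population reference point derive from it.
* **Cohorts.** Default 30 BPD-like and 31 control-like participants.
  Parameters draw from the same hierarchy the fitted model assumes —
  median learning rate 0.3 (logit-scale spread 0.5), median noise 0.7
  (log-scale spread 0.2), reference weight 0.3 where applicable — and the
  default generating model is the fine learner without reference points.
* **Sessions.** Profiles in the design order; trait order re-shuffled per
  participant and block; responses are model predictions plus Gaussian
  noise, rounded and clipped; feedback is the profile's true rating. An
  optional flag marks one or two whole trait words invalid per participant
  (emulating not-understood items); default off.

What the generator does **not** emulate: real trait-word semantics (labels
are a configurable word list), response times, order effects in the
self-rating phase, participant dropout, or any dependence of the noise on
trial or valence. Passing recovery tests therefore show that the estimation
and comparison machinery is correct *under the generating assumptions* —
they do not show that the models describe real behavior.

## Problem sizes and numerical choices

Recovery checks run at deliberately reduced scale: parameter recovery uses
10 replicates of 16 participants x 240 trials (reduced 800/600 MCMC);
model recovery uses 10 replicates of 12 participants with fast-mode
cross-validation; the analysis drivers run the full 61-participant study
with 1500/1000 draws, and the extended-V0 contrast on 8 participants per
group. These sizes are the package's choices for a desk-scale
demonstration; all are configurable.

Other numerics: alpha grids use 101 points (point estimates, with closed
form in w) or 257 (likelihood cache); SPI requires >= 100 draws; the
cluster bootstrap for PE trends resamples participants (>= 200 resamples)
and reports percentile intervals, clamped to contain the point estimate;
zero-variance trait columns get zero similarity weight with a warning;
degenerate folds (empty training sets, < 3 participants) raise instead of
returning numbers.

## Known limitations

* The descriptive PE-trend machinery (OLS slope + cluster bootstrap) is a
  transparent stand-in for mixed-effects inference, not equivalent to it;
  with few participant clusters the bootstrap CI undercovers slightly.
* Walker-as-chain rhat/ESS overstate non-convergence for ensemble samplers;
  treat the warning flag as conservative.
* The 2xSE rule is applied pairwise without multiplicity correction, by
  design.
* The Gaussian likelihood ignores the discreteness and bounds of the
  response scale; recovered noise scales absorb rounding variance
  (~ +1/12).
* Condition-level V0 in the extended models assumes participants within a
  condition share initial expectations up to the hierarchical shrinkage;
  participant-level V0 is not identifiable in this design.
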