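# Methods

`aukipm` implements an integrated population model (IPM) for colonial auks
with delayed recruitment, together with the post hoc analyses that turn a
fitted model into demographic conclusions: a transient life table response
experiment (tLTRE), process correlations, and linear trend tests.  Because
the field data such models are built for are typically access-restricted,
the package treats the synthetic-data generator as a first-class component:
every claim the package makes is checked by generating data whose true
parameters are known and demonstrating that the pipeline recovers them.

## Population model

The model is female-based with a pre-breeding census and five classes in
fixed order (N1, N2, N3, N4, Nimm): one-, two-, three-year-old pre-breeders,
resident breeders aged 4+, and breeding-age immigrants.  Only the 4+ class
and immigrants breed.  With year-specific productivity f_t (chicks fledged
per pair), first-year apparent survival α1_t, adult apparent survival α2_t,
and a constant immigration-plus-noise rate ω, the stochastic state process
is

    N1,t+1   ~ Binomial(Ntot,t,            f_t/2 · α1,t)
    N2,t+1   ~ Binomial(N1,t,              α2,t)
    N3,t+1   ~ Binomial(N2,t,              α2,t)
    N4,t+1   ~ Binomial(N3,t + Ntot,t,     α2,t)
    Nimm,t+1 ~ Poisson(ω · (N1+N2+N3+N4)_t)

with breeding population Ntot,t = N4,t + Nimm,t.  Pair-count surveys, which
exist only in a sparse subset of years, observe y_t ~ Poisson(Ntot,t).
Realized growth is λ_t = Ntot,t+1 / Ntot,t.  The f/2 halving is the
single-sex convention; "apparent" survival confounds mortality with
permanent emigration, and ω absorbs both true immigration and unmodelled
process error, which is why it is a nonnegative rate rather than a
probability.

The immigrant class contributes recruits and survivors (rows N1 and N4 of
the expected-value projection matrix) but the Nimm row draws only on the
four resident classes: immigrants already present graduate into N4, so an
Nimm→Nimm loop would double-count them.

Initial abundances follow the stable stage structure of the first-year
projection matrix, anchored at a configured initial pair count, with the
immigrant class at its prior mean (Poisson with mean 50, the configured
per-year immigrant intensity).  We initialize all pre-breeder classes from
the stable-stage eigenvector; the alternative of seeding only the immigrant
class stochastically is noted in the code but not used, as sensitivity of
the fits to the initial split is minimal at colony scale.

## Mark-recapture submodel

Encounter data are season counts c_{i,t} (how many times individual i was
seen), not binary detections.  Three latent layers generate them:

* alive state z_{i,t} ~ Bernoulli(φ_{i,t-1} z_{i,t-1}), where φ is α1 for
  the first transition after hatch-year marking and α2 afterwards;
* availability k_{i,t} ~ Bernoulli(z_{i,t} γ_{k_{i,t-1}, age_{i,t-1}}):
  temporary emigration as a Markov chain, with entry probability γ1 and
  persistence γ2 each age-specific (ages 1, 2, 3, 4+) to capture the
  gradual return of pre-breeders to the colony;
* counts c_{i,t} ~ Poisson(k_{i,t} · ε_{g(age),t} · h_i), with group mean
  encounter rates ε for pre-breeders (ages 1–3) and breeders (4+), and an
  individual heterogeneity multiplier h_i ~ Gamma(θ, θ) (mean 1; smaller θ
  = more individual spread).  Detection probability per season is
  p = 1 − exp(−ε).

Chicks marked in the burrow are counted at marking, forced off-colony the
following season, and re-enter through the age-1 availability row.  Adults
are marked as (and stay) 4+.

**Conditioning on the marking event.** Individuals enter the data only by
being encountered, so marked birds are a detection-biased sample of h.  The
likelihood of a history is the joint probability of all its counts (plain
gamma-Poisson at the marking occasion) divided by the marginal probability
of at least one marking-season encounter, 1 − (θ/(θ+ε_m))^θ.  The simulator
implements the same event by redrawing the pair (h_i, c_mark) jointly until
c_mark ≥ 1 — resampling the count alone would leave h unbiased and break
the correspondence between generator and likelihood.

**Marginalization.** The likelihood integrates the latent layers exactly:
a three-state forward recursion (dead / alive-unavailable / alive-available)
over seasons, run at fixed quadrature nodes for h and combined with the
node weights.  The quadrature is Gauss–Laguerre-type for the normalized
Gamma(θ, θ) measure, built from the Jacobi matrix with weights evaluated
through the orthonormal-polynomial identity in scaled arithmetic (the
textbook weight formula overflows near θ ≈ 170, and eigenvector-squared
weights lose relative accuracy exactly where tilting needs them).  Each
history's rule is exponentially tilted by half its maximum total encounter
rate, which keeps 32 nodes accurate to ~1e-13 even at θ = 0.5 where the
untilted rule needs hundreds of nodes.  Default 32 nodes; the sampler uses
16 (reproducing the 64-node value to ~3e-9 at literature-scale θ).

An exhaustive oracle (`brute_force_loglik`) enumerates every latent path
and integrates h analytically per path; it shares no code with the forward
recursion and anchors the test suite.

## Productivity submodel

J_t ~ Binomial(B_t, f_t) for B_t monitored burrows (single-egg clutch, so
a burrow fledges at most one chick).

## Temporal structure and priors

Year effects are logit-scale: survival effects have fixed SD 1 (a literal
reading of a unit-variance specification; the SD is a config field), and
productivity effects have an estimated SD σ_f.  Productivity effects are
parameterized *centered* (the effects themselves, prior N(0, σ_f)): with
60–100 burrows per year the data dominate each effect, which is the regime
where the centered form is well conditioned.  Encounter rates optionally
take a shared log-scale year-effect series (one series added to both group
means, SD estimated) — off by default, and off in the shipped scenarios;
the group-specific-series alternative is noted here as the flagged option.

Priors where nothing is stated elsewhere: Uniform(0,1) on all
probability-scale means (survival, productivity, availability),
ω ~ Uniform(0, 0.5), σ_f and σ_ε ~ Half-Normal(1), θ ~ Gamma(1, 0.05)
(mean 20, SD 20 — wide on both sides of literature-scale heterogeneity),
log ε group means ~ Normal(0, 1.5²).  All are config-overridable
(`PriorConfig`).

## Fitting engines

The **marginal engine** (default) integrates the latent abundances out of
the count submodel with a moment-matched Gaussian (Kalman) filter: each
binomial/Poisson transition kernel is replaced by a Gaussian with the same
conditional mean and variance, and the Poisson observation by a Gaussian
with variance equal to the predicted breeding population.  At colony scale
(hundreds to thousands of pairs) this approximation is excellent, and it
reduces the sampling problem to ~3T+14 continuous parameters.

Sampling is Markov chain Monte Carlo with proposals shaped — never the
target — by a Laplace approximation: posterior mode by quasi-Newton with
batched finite-difference gradients (hierarchical SDs held fixed during the
mode search and then set to their conditional modes, because the joint
density of a centered hierarchy is unbounded along σ→0), curvature by a
finite-difference Hessian with eigenvalue repair.  The sampler combines

* Metropolis-within-Gibbs block updates whose proposals are the Gaussian
  conditionals of the Laplace/empirical approximation (multivariate-t tails,
  df 7, so a mis-shaped conditional cannot trap a chain);
* a tailored conditional update of the productivity year effects (per-year
  Newton-mode proposals recomputed from the current state every sweep);
* full-vector preconditioned Crank–Nicolson (autoregressive) refresher
  steps around the empirical posterior Gaussian, with the step parameter ρ
  tuned in a short discarded window;
* scalar random-walk refreshers for ω and the hierarchical SDs; and
* prior-only "translation" moves along each mean-versus-year-effects ridge.

After burn-in the proposal geometry is rebuilt from the empirical
covariance of the burn draws blended with the Laplace covariance, then
frozen.  Every move is a valid Metropolis–Hastings kernel, so the chain is
exact MCMC regardless of how crude the approximations are.  Four chains
start overdispersed (bounded per-coordinate); convergence is reported as
rank-based R-hat and effective sample size (arviz) on all scalar
parameters, with targets R-hat < 1.05 and ESS ≥ 200 — deliberately strict;
failing either returns the draws flagged unconverged with the offending
parameters listed, never a silent pass.

Latent abundance trajectories are recovered per retained draw by
forward-filter backward-sampling under the same Gaussian approximation, so
breeding-population, realized-growth and stage-proportion series are
genuine posterior draws.  All summaries are computed from draws, never from
plug-in transforms of summaries.

The **discrete engine** keeps the state process exact: Metropolis-within-
Gibbs alternating a parameter block with single-site integer random-walk
updates of every abundance class-year (year 1 pinned to the stable-stage
allocation).  It mixes far more slowly and is provided for small problems
and cross-checks; the shipped recovery and calibration tests run on the
marginal engine, whose Gaussian error is negligible at the population sizes
involved, so that twenty replicate fits finish in minutes rather than days.

Single-dataset fits (`fit_cmr_only`, `fit_productivity_only`) are the same
posterior with streams removed; parameters informed only by omitted streams
revert to their priors, which doubles as a correctness check.

## Transient LTRE

The decomposition targets the growth of the *all-class* total, because
recruitment (f, α1) and stage structure act on it contemporaneously:

    λ(θ) = (f/2)·α1·(n4 + nimm) + α2·(n1+n2+n3+n4+nimm) + ω·(n1+n2+n3+n4)

with n the stage proportions.  At the stable stage structure this equals
the leading eigenvalue of the projection matrix exactly.  The breeding-
population ratio Ntot,t+1/Ntot,t reported by the fits is a distinct, lagged
quantity and is labelled separately.  First-order contributions are
C_ij = cov_t(θ_i, θ_j) s_i s_j with sensitivities s = ∂λ/∂θ at the temporal
mean; λ is multilinear, so the analytic gradient is exact.  Annual-change
contributions use midpoint sensitivities (exact for the bilinear terms,
first-order for the one trilinear term).  ω is carried in the parameter set
with zero temporal variance so its sensitivity is still reported.  The
decomposition runs on posterior-mean year series by default; a per-draw
mode returns one decomposition per retained state draw for interval
summaries.  Process correlations are Pearson correlations of the annual
rate series computed within each posterior draw and summarized across
draws.

## Trend tests

Ordinary least squares of annual posterior-mean rates on calendar year
(centered for conditioning; slope per year; two-sided t test).  Regression
on means, not draws, matching standard post hoc practice; a mask drops
years whose estimates are structurally floored — terminal first-year
survival estimates are lower bounds until the cohorts reach recruitment
age, so the last few years are excluded from trend and mean summaries.
A constant series reports slope 0 with p = 1 (the t statistic there is
numerical noise).

## Synthetic scenarios

The generator draws year series from the same structure the model assumes
(survival effects SD 1 on the logit scale, productivity effect SD 0.5,
constant encounter rates), so recovery tests are exactly calibrated.
Shipped scenarios:

* **reduced** (default test scale): 15 seasons, ~1200 initial pairs, 100
  chicks + 40 adults marked per year, 80 monitored burrows, surveys every
  4th year; truth α1 = 0.30, α2 = 0.85, f = 0.55, ω = 0.08, θ = 39,
  γ1 = (0.05, 0.2, 0.4, 0.5), γ2 = (0.3, 0.5, 0.7, 0.9), ε = (1.0, 2.5).
* **calibration**: 10 seasons, ~1000 pairs, 60 chicks + 25 adults per year,
  60 burrows, surveys every 3rd year — small enough that twenty replicate
  fits run inside a routine test session.
* **paper-scale**: 22 seasons with six surveys at the scale of a large
  stable colony (~8000 pairs) or a small growing one (~400 pairs, higher
  immigration, lower θ).

What the generator does *not* emulate: band loss and misread bands,
within-season robust-design structure, observer effects, year-varying
marking effort, density dependence, environmental covariates.  Passing
recovery tests therefore demonstrate that the estimator is correct and
calibrated *under the model's own assumptions* — they cannot certify
robustness to the ways real colonies violate them.

## Numerical choices

* Stage order (N1, N2, N3, N4, Nimm) is fixed everywhere and asserted in
  constructors; years map to 0-based indices internally, calendar years at
  file boundaries only.
* Dominant-eigenvalue check: relative modulus gap ≥ 1e-8, else an explicit
  error naming the gap.
* Identical encounter histories are collapsed with multiplicities before
  likelihood evaluation (exact; the cost scales with distinct histories).
* A compiled (numba) scalar-loop kernel repeats the forward recursion for
  the sampler's inner loop; equivalence with the numpy reference route is
  asserted in the tests, and the enumeration oracle anchors both.
* Survey counts are required integer; quadrat extrapolation rounds.
* ε = 0 at a marking occasion takes the analytic limit (the truncated count
  concentrates on 1).
* Realized growth over a zero denominator returns NaN with a warning, never
  a silent drop.

## Known limitations

* The Gaussian marginalization of the count submodel is an approximation;
  it is excellent above a few hundred pairs but untested below ~50, where
  the discrete engine should be preferred.
* ω is weakly identified when surveys are very sparse; its posterior then
  leans on the Uniform(0, 0.5) prior bound.
* γ2 for ages 1–2 is nearly prior-only in realistic designs (few available
  pre-breeders are re-observed the following season); intervals are honest
  about this.
* Mean survival on the logit scale is identified only through the year-
  effect prior when effects are large; reported "mean" rates are the
  inverse-logit of the mean parameter, not the average of annual rates.
* At default draw budgets a minority of replicate fits miss the strict
  ESS target on a few availability parameters; they are flagged, and the
  coverage of credible intervals is unaffected in the calibration tests.
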