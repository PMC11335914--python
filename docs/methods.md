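# Methods

## The model

`rdex` implements a hybrid race model of stop-signal task performance. On
every trial two evidence accumulators — one per response option — race from
zero toward their thresholds. Each accumulator is a single-boundary Wiener
diffusion with drift `v > 0`, effective threshold `b = B + A > 0` and unit
diffusion coefficient (fixed for identifiability), so its finishing-time
density is the Wald (inverse-Gaussian) distribution

    f(t) = b (2 pi t^3)^(-1/2) exp(-(v t - b)^2 / (2 t)),   t > 0,

shifted by a non-decision time `t0` (stimulus encoding plus motor
execution). The observed response is the accumulator that finishes first;
the RT is its finishing time plus `t0`. Start-point variability (`A > 0`,
uniform start in `[0, A]`) is supported by the simulator but fixed at
`A = 0` in the likelihood, so `b = B` exactly; fast errors requiring
`A > 0` are outside the fitted model's scope.

On a randomly interleaved 25% of trials a stop signal appears at the
stop-signal delay (SSD) and launches a stop runner that races the go
accumulators. Rather than a third accumulator — which makes the model
unidentifiable because the stop runner's shift parameter must be inferred
from wholly indirect evidence — the stop runner's finishing time (measured
from stop-signal onset) is described by an ex-Gaussian distribution
(Gaussian(mu, sigma) convolved with Exponential(tau)), truncated below at
`l = 0.05` s to rule out physiologically impossible stopping latencies and
renormalized. The truncated mean, estimated by Monte Carlo
(`trunc_exg_moments`, default 10^6 draws with an explicit seed), is the
model's summary SSRT.

Two attention-failure probabilities complete the model: with probability
`pgf` the go runners are never launched (the trial is an omission
regardless of type) and with probability `ptf` the stop runner is never
launched (stopping is impossible on that trial). Both are estimated on the
probit scale (`zgf`, `ztf`).

Trial likelihoods follow from independence of the runners:

* go response `i` at time `t`: `(1 - pgf) f_i(t - t0) S_j(t - t0)` with
  `S` the Wald survival; go omission: `pgf`;
* stop-trial response (signal-respond): the same product additionally
  multiplied by `ptf + (1 - ptf) S_stop(t - SSD)`;
* successful inhibition:
  `pgf + (1 - pgf)(1 - ptf) Int f_stop(s) S_i(s + SSD - t0) S_j(s + SSD - t0) ds`
  over the stop runner's support, `s` on the stop clock.

With these definitions the three outcome probabilities of each trial type
sum to one, which the test suite verifies by quadrature. A published form
of the go-trial likelihood adds `pgf` to the response density itself;
taken literally that allocates more than unit mass across outcomes, so the
package implements the normalized mixture above (the omission carries the
`pgf` mass), consistent with the structure of the inhibition term.

The likelihood contains no explicit deadline term: responses later than
the 2 s deadline are recorded by the simulator as omissions (go) or
inhibitions (stop), and the fitted `pgf` absorbs the (small, ~0.5%)
censored mass. This is a deliberate, mild misspecification matching the
standard treatment of the paradigm.

## Design mapping

The default experimental design fully crosses four two-level factors —
block type (blockwise vs trialwise bias cuing), bias cue (blue vs orange),
difficulty (easy vs hard) and stimulus (majority blue vs orange) — for 16
cells with two accumulators each. Selective-influence assumptions tie
parameters across cells:

| type  | factors                          | count |
|-------|----------------------------------|-------|
| t0    | none                             | 1     |
| B     | block type x bias x accumulator  | 8     |
| v     | block type x difficulty x match  | 8     |
| mu, sigma, tau | none                    | 3     |
| zgf, ztf | none                          | 2     |

for 17 go and 22 total free parameters. Thresholds implement cue-induced
response bias (they may not depend on difficulty, whose level is
unpredictable at the time the threshold is set); rates carry stimulus
quality (match vs mismatch, easy vs hard) and attentional demands (block
type), with the rates for blue and orange stimuli assumed equal. A
descriptive ex-Gaussian account of the go runners, by contrast, needs 3
parameters per cell per accumulator (96 go, 101 total), which is the
comparison the parameter-count helpers reproduce.

`ParameterMap` resolves any (cell, accumulator, type) triple to a flat
index by enumerating the *reachable* factor-level combinations; this
matters when a derived factor (e.g. match = accumulator == stimulus) is
assigned alongside its constituents, where the naive level crossing counts
combinations that never occur. Canonical ordering (types:
t0, B, v, mu, sigma, tau, zgf, ztf; levels alphabetical) makes the flat
vector a stable serialization target.

## Simulator

`make_schedule` reproduces the study structure: two sessions (one
blockwise, one trialwise), eight 60-trial experimental blocks per session
with exactly 15 pre-assigned stop trials each (960 trials, 240 stop).
Difficulty is balanced within block; the bias cue is fixed per block in
blockwise sessions (balanced across blocks) and drawn per trial in
trialwise sessions; the stimulus matches the cue with 70% probability (cue
validity affects stimulus frequencies only — cue identity, not its
correctness, enters the parameter map). SSD follows a one-up one-down
staircase (start 0.2 s, step 0.05 s, floor 0 s, no ceiling, state
persisted across blocks and sessions), which tracks the ~50% inhibition
point; responses after the 2 s deadline are recorded as omissions or
inhibitions. Exact accumulator ties are measure-zero and broken by
`argmin`'s first-index rule.

What the generator does not emulate: practice and go-only familiarization
blocks, feedback effects, sequential dependencies (post-stop slowing),
RT contaminants and lapses other than the two failure probabilities, and
any parameter drift over time. Passing recovery tests on these data
therefore show that the estimation machinery inverts the model itself,
not that the model fits any particular empirical population.

## Priors and estimation

Independent truncated-normal priors per parameter type: t0 ~ TN(0.35,
0.1) on [0.1, 1] s; B ~ TN(1, 5) and v ~ TN(2, 5) on [0, inf); mu ~
TN(0.5, 1), sigma, tau ~ TN(0.1, 1) on [0, 4] s; zgf, ztf ~ N(-2, 2)
(failure rates centered near 2%). Hierarchical estimation places
truncated-normal population distributions (same bounds) over each
parameter with the above as priors on the locations and Exponential(1)
priors on the scales; population distributions are independent across
parameters.

Sampling is differential-evolution MCMC: a population of chains (default
three per free parameter, 66 for the default model) updated in two
alternating half-populations so that every posterior evaluation is
vectorized across chains. Crossover proposals are
`x' = x + gamma (x_a - x_b) + U(-1e-3, 1e-3)` with `gamma =
2.38 / sqrt(2 d)` and partners drawn from the other half; every tenth
iteration uses `gamma = 1` (mode jumping), and a random 10% of iterations
replace crossover with a snooker update (proposal along the line through
the chain and an anchor state, with the `|x' - z|^(d-1)` Jacobian
correction), which substantially improves traversal of the model's
elongated t0-threshold-rate ridge. During burn-in a migration step
occasionally circulates states around a random chain cycle. Burn-in ends
when split-population R-hat falls below 1.1 (or an iteration cap);
retained draws default to 250 per chain at thinning 5. Bounded parameters
are handled by prior rejection, not reparameterization.

Start values. Drawing chains from the prior leaves the population days of
mixing away from the posterior and can trap it in a well-known spurious
solution with `t0` pinned at its lower prior bound and inflated
thresholds and rates. `sample_individual` therefore defaults to a
mode-centered initialization: a data-driven anchor (non-decision time
from the fastest RT, rates from threshold over mean decision time,
go-failure rate from the observed omission rate), polished by Nelder-Mead
and then a bounded quasi-Newton step with batched finite-difference
gradients; chains start from the Laplace (finite-difference Hessian)
approximation at that mode, so the population carries the posterior's
correlation structure from the first iteration. Flat curvature directions
are capped at a modest scale because a DE population much wider than the
posterior cannot contract (no proposals are accepted). Prior-drawn starts
remain available (`init="prior"`). Hierarchical fits initialize each
subject block the same way.

Numerics. All kernels are evaluated in log space via scaled
complementary-error functions; the ex-Gaussian evaluations are stable for
sigma, tau down to 1e-4, and the compiled likelihood returns zero below
that floor (a tau -> 0 stop runner is a degenerate model and the region
otherwise acts as a numerical-artifact attractor for optimizers). The
inhibition integral is computed two ways: the reference scalar path uses
adaptive quadrature (relative tolerance 1e-6) on
`[l, mu + 10 sigma + 20 tau]`; the compiled path uses fixed panels —
Gauss-Legendre across the Gaussian bump `[mu - 6 sigma, mu + 6 sigma]`
and exponentially-transformed Gauss-Legendre panels on tail segments at
`c + {1, 3, 7} tau` — giving absolute error below ~1e-5 at the default
order (16-node bump, 8-node tails) and ~2e-4 at the reduced order used
for recovery fits (12/6). The compiled path has a numba kernel and an
equivalent vectorized numpy fallback; both agree to ~1e-10 and are
cross-checked in the tests.

## Assessment machinery

Posterior predictive checks draw whole parameter vectors (not independent
marginals) from the retained chains, simulate replicates with the observed
SSDs and per-cell trial counts, and summarize defective-CDF percentiles
(10/30/50/70/90; the percentile rule interpolates the empirical CDF at
p = k/n, so the 10th percentile of {0.01..1.00} is exactly 0.10), the
inhibition function and median signal-respond RT over equal-count SSD
bins (counts differ by at most one when ties permit; fewer trials than
bins reduces the bin count with a warning).

The bimodality diagnostic formalizes what is usually judged from plots: a
Silverman-bandwidth KDE's modes, with a secondary mode requiring at least
10% of the sample's mass and a separating density dip below 80% of the
smaller peak (shallow ripples on imperfectly mixed draws are merged), plus
a boundary-pileup flag when mass stacks against a prior bound. Thresholds
are arguments, not constants.

## Recovery study conditions

The recovery harness simulates complete staircase datasets per truth
vector, fits each individually with the same machinery, and reports
pooled true-vs-estimated correlations per parameter type (thresholds and
rates pooled across their 8 parameters, as in combining them into single
panels), 95%-interval coverage, bias and mode diagnostics.

Because the reference truths (per-participant posterior means from an
empirical dataset) are not part of this package's inputs, the default
truth generator anchors at the reported condition effects —
match-mismatch rate differences of ~2.4 (easy) and ~1.37 (hard) with
slightly larger rate contrasts under trialwise cuing, congruent vs
incongruent thresholds ~1.69/1.92 with threshold-bias effects of ~0.12
(blockwise) and ~0.33 (trialwise), shared t0 = 0.25 s, stop runner
(mu, sigma, tau) = (0.2, 0.04, 0.08) s (mean SSRT ~0.28 s), pgf = 0.02,
ptf = 0.07 — and jitters them between truth sets with truncated-normal
noise (SDs: t0 0.04, B 0.20, v 0.40, mu 0.04, sigma 0.015, tau 0.025,
zgf/ztf 0.40 probit units), chosen once as plausible between-participant
variability.

The desk-scale study runs 6 truth sets x 20 replicates of 960-trial
datasets with reduced MCMC (24 chains, mode-centered starts, burn-in
capped at 350 iterations, 100 draws per chain at thinning 6,
reduced-order quadrature); a full-scale study (18 x 200, full chain
counts and burn-in) uses the same code path with larger settings.

Known limitations of individual estimation, reproduced rather than hidden
by this package: in some datasets the posterior concentrates on the
displaced ridge solution (low t0, inflated B and v) even when fully
converged — the sampling distribution of posterior means across
replicates is then bimodal with one mode at the truth — and weakly
identified stop-runner shape parameters (especially sigma, constrained
only by ~240 stop trials) recover with substantial noise relative to
realistic between-participant spread. Hierarchical estimation with
population-level shrinkage is the recommended remedy and is what the
boundary-regime test exercises.
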