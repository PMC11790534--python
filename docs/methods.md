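# Methods

## The model

Every analysis in this package rests on the two-boundary Wiener diffusion
(drift–diffusion) model of two-alternative forced-choice decisions. On each
trial a noisy evidence signal

    dX = v dt + s dW,    X(0) = z * a,

accumulates between two absorbing boundaries at 0 and `a`; the boundary hit
first determines the choice, and the response time is the first-passage
time plus a non-decision time `t` covering stimulus encoding and motor
execution. Four parameters are estimated:

| symbol | meaning | units | domain |
|---|---|---|---|
| `v` | drift rate (mean evidence accumulation) | evidence/s | real |
| `a` | boundary separation (caution) | evidence | > 0 |
| `z` | relative starting point (bias) | fraction of `a` | (0, 1) |
| `t` | non-decision time | s | >= 0 |

The within-trial diffusion coefficient is fixed at `s = 1`, the convention
of the major hierarchical DDM toolboxes, so parameter magnitudes are
comparable with that literature. Intertrial variabilities (`sv`, `sz`,
`st`) are fixed at zero throughout: the basic four-parameter model, not the
"full" DDM, is what all fits here use.

### Likelihood

The first-passage density at the lower boundary factorises into an
exponential tilt and a standardised density `f1(u, w)` of the scaled time
`u = t_dec / a^2`. `f1` has two classical series representations — a
small-time expansion over image charges and a large-time sine series — and
the implementation evaluates whichever needs fewer terms for a requested
truncation error (1e-7 inside MCMC, 1e-10 for user-facing density calls),
the standard dual-series approach for this density. The two expansions
agree to better than 1e-8 in their overlap region (tested), and the density
integrates to one over both boundaries to 1e-4 by adaptive quadrature
across a parameter grid spanning the regimes that occur in fitting. The
upper-boundary density is obtained by reflection (`v -> -v`, `z -> 1-z`).
At `rt <= t` the density is zero (the boundary point is measure zero), and
the log likelihood of a trial set is `-inf` whenever any trial violates the
support — proposals that do so are simply rejected during sampling, so no
response-time trimming is ever applied to the data.

### Forward simulation

The simulator is an Euler–Maruyama walk with default step `dt = 1e-4` s and
a 20 s decision-time cap (capped walks are flagged, not looped forever).
Discrete crossing detection delays absorption by an `O(sqrt(dt))` bias; the
standard continuity correction (boundaries widened by
`beta * s * sqrt(dt)`, `beta = -zeta(1/2)/sqrt(2*pi) ~ 0.5826`) accounts
for it almost exactly, which the tests exploit: uncorrected comparisons use
3-standard-error tolerances, and the mean-RT oracle test checks the
corrected prediction. At `dt = 1e-4` the residual bias in choice fractions
is well below Monte-Carlo noise at the sample sizes used.

## Synthetic experiments

The generator reproduces the *design structure* of the two experiments the
package targets — split-second left/right anticipation of handball penalty
throws on a touch screen:

* Experiment 1: 27 subjects x 4 blocks x 100 trials, response modality
  (pointing vs swiping) alternating between blocks, starting modality
  counterbalanced across subjects; no cues.
* Experiment 2: 30 subjects x 4 blocks x 96 trials; blocks 1–2 uncued
  baseline, blocks 3–4 show a 75/25 probability cue for the left (or right)
  throw direction, switching at 50% of the block and counterbalanced
  between blocks and subjects. Trials whose actual direction matches the
  cued majority side are congruent, the rest incongruent.

Default ground truth (all overridable): `|v| = 1.5`, `a = 2.0`,
`z0 = 0.55` (the rightward bias seen in this task), `t_point = 0.55` s,
`t_swipe = 0.45` s, congruency drift modulation `dv = 0.3`, cue-induced
starting-point shift `dz = 0.05`. Subject-level values are sampled on
transformed scales — drift: identity (sd 0.3), boundary and non-decision
time: log (sd 0.2, i.e. ~20% coefficient of variation), starting point:
logit (sd 0.2) — so draws respect the parameter domains without rejection
sampling. A subject's deviations across the cells of one parameter share an
exchangeable correlation `rho_subject` (default 0.6), which makes
cross-modality correlations of subject parameters a recoverable feature
rather than an artefact. Stimulus direction is balanced 50/50 per cue
segment by default; a flag makes cued segments follow the advertised 75/25
frequencies instead. The cue switch sits at trial 48 of 96 (50% of the
block).

What the generator does *not* emulate: finger trajectories, video timing
and kinematic-information onset, practice trials, sequential (trial-order)
effects, response-time contaminants, and intertrial parameter variability.
Passing recovery tests therefore show that the estimation machinery is
correct for data of this structure — not that real behavioural data obey
the four-parameter model.

## Hierarchical estimation

For each diffusion parameter and each design cell declared by a
`ModelSpec`, the population model is Normal on the transformed scale
(identity/log/log/logit for `v`/`a`/`t`/`z`), with subject values drawn
from it. Priors (overridable via `Priors`) are weakly informative on those
scales: group means `v ~ N(0, 2^2)` under stimulus coding (`N(1, 2^2)`
under accuracy coding, where above-chance performance is expected),
`log a ~ N(log 1.5, 1)`, `log t ~ N(log 0.4, 1)`, `logit z ~ N(0, 1.5^2)`;
group standard deviations are half-Normal(0.5) on the transformed scale.
Placing the priors on the sampling scale keeps every draw in-domain and
lets the group-mean update stay conjugate; the support constraint `t < rt`
is enforced by the likelihood itself.

Boundary codings follow the two questions asked of the data. Stimulus
coding (upper boundary = "right") fits a single drift magnitude per cell
whose sign follows the stimulus direction, so the starting point captures
lateral response bias — used for the modality models M1–M4 and the cue
manipulation check. Accuracy coding (upper = correct) is used for the
congruency model, where performance rather than laterality is of interest.

### Sampler

Adaptive Metropolis-within-Gibbs with a centred parameterisation:

1. two sweeps per iteration of single-site random-walk updates of every
   subject-level parameter block (the second sweep roughly doubles the
   effective sample size per stored draw at modest cost, since each block
   only re-evaluates the likelihood of its own trials);
2. a conjugate Gibbs draw for each group mean;
3. five random-walk Metropolis sub-steps on the log of each group standard
   deviation (its conditional involves no trial likelihood, so this is
   nearly a full conditional draw).

Proposal widths adapt during burn-in only (multiplicative updates every 25
iterations toward 44% acceptance, the one-dimensional optimum), leaving the
post-burn-in kernel fixed and draws exactly reproducible under a seed.
Chains are spawned independently from one seed sequence; two chains are the
default so the Gelman–Rubin statistic (classic between/within variance
ratio; reported for every stored parameter) is always available. "Draws"
counts total iterations per chain including burn-in, matching the
toolbox convention of the literature this package follows (5000 draws, 500
burn-in at full scale); burn-in draws are retained in the stored chains and
discarded from all summaries.

The deviance trace is recorded every iteration, and DIC uses the classic
form `DIC = D_bar + p_D`, `p_D = D_bar - D(theta_bar)`, with the plug-in
deviance evaluated at the posterior means of the subject-level parameters
on the sampling scale mapped back to the natural scale.

### Hypothesis tests

Directional claims are posterior probabilities `P_p|D(theta_1 > theta_2)`
estimated from draws: paired within draw when both parameters come from one
joint fit (the default when draw counts match), by seeded product
resampling across separate fits. Ties count one half, so complementary
probabilities sum to one exactly. The significance convention is the
symmetric 5%-overlap rule: a claim is flagged iff `P >= 0.95` or
`P <= 0.05`. This is a posterior summary, not a calibrated frequentist
test; on null synthetic data the flag rate is about 5–10% (checked, and
reported by the acceptance script), not exactly 5%.

Cross-modality consistency is summarised by the Pearson correlation of
subject-level posterior means between modalities, with
`df = n_subjects - 2` and a two-sided p-value from the t transform.

## Problem sizes and numerical choices

Scales used by the test suite and the acceptance script were chosen so a
full validation runs on one CPU in minutes:

* density validation grid: `v in {-2,0,2} x a in {1,2} x z in {0.3,0.5,0.7}`;
  chi-square agreement against 1e5 Euler–Maruyama trials at `dt = 1e-4`;
* choice-probability checks: 2e4 trials per grid point, `dt = 2.5e-4`;
* parameter recovery: 10 subjects x 384 trials (the Experiment 2 shape),
  1500 draws / 300 burn-in / 2 chains, 10 independent seeds; the recovery
  truth removes the modality split of `t` and sets `rho_subject = 1`, so
  the fitted model (`exp2_generative`: drift by congruency, starting point
  by cue, stimulus coding) is *exactly* the generating process and group
  means are compared on the sampling scale where the hierarchy is Normal;
* model selection: 20 replicates of 6 subjects x 96 trials generated with a
  modality-split non-decision time and shared drift, all four modality
  models fitted at 600 draws / 200 burn-in.

Degenerate inputs are errors, not silent repairs: empty trial tables,
design cells without trials, factors with a single level, single-chain
Gelman–Rubin requests, and comparisons of fits on differing data all raise
with a message naming the offender. When between-chain variance is exactly
zero the Gelman–Rubin statistic is reported as 1.0.

## Known limitations

* Single-site random-walk updates mix more slowly than gradient-based
  samplers; at the default reduced scales, subject-level parameters
  occasionally show R-hat near 1.05–1.08. Pipelines abort (non-zero exit)
  when any R-hat exceeds 1.1.
* The accuracy-coded congruency model is deliberately misspecified with
  respect to the stimulus-coded generator (as it is with respect to real
  data); its cells have no single ground-truth value, which is why recovery
  is scored on the matching stimulus-coded model.
* No intertrial variability, collapsing bounds, or contaminant mixtures;
  data containing fast guesses will inflate `z`/`v` estimates.
* DIC is the only comparison criterion implemented (matching the target
  analyses); WAIC/LOO would require per-trial likelihood storage and are
  left out deliberately.
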