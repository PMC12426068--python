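# Methods

## The model

`mptsource` implements a multinomial processing tree (MPT) for recognition
memory with two-dimensional source attribution. Studied statements come from
one of four sources crossing *veracity* feedback (true/false) with
*importance* feedback (important/unimportant); at test each item (36 targets,
18 distractors) receives an old/new decision and, for "old" decisions, an
attribution to one of the four source combinations, giving five response
categories per item type (new, old-TI, old-TU, old-FI, old-FU).

The tree is a two-high-threshold recognition architecture extended with a
source stage. For a target from source (i, j):

* with probability `D_ij` the item is detected as old;
* a detected item's source combination is retrieved **jointly** with
  probability `d_ij` (a bound compound of both features, producing
  stochastic dependence between the two attributions);
* if joint retrieval fails, each dimension is retrieved **independently**:
  veracity with probability `e_ij^ver` (otherwise guessed "true" with
  `a_ver`), then importance with `e_ij^imp` (otherwise guessed "important"
  with `a_imp|true` or `a_imp|false`, conditional on the *veracity response*);
* an undetected item is guessed "old" with probability `b`, in which case the
  source is guessed with the `g` parameters (mirroring the `a` structure);
* distractors are detected as new with `D_new`, otherwise enter the same
  old-guessing branch.

The category probabilities are sums of root-to-leaf branch products. Two
independent representations are maintained: a closed-form vectorised algebra
(`model.category_probability_matrix`) and an explicit path enumeration
(`paths.enumerate_tree_paths`, 15 paths per target type, 6 per distractor),
which also drives the `.eqn` export. The test suite requires them to agree to
1e-12; they agree to machine precision.

Guessing "false" is parameterised as `1 - a_ver` (and `1 - g_ver`); no
separate parameter exists. The veracity-then-importance branch order is a
presentation choice only — the independent-retrieval stage factorises, so the
category probabilities are invariant to it; the importance-guessing
parameters are conditioned on the veracity *response*, which is the
substantive modelling commitment.

### Constraints

The standard analysis equates `D_new = D_TI`, all `g` with the corresponding
`a`, and the independent-retrieval parameters across source combinations
within each dimension (`e_ver`, `e_imp`), reducing the 24 tree parameters to
14 free parameters: `D_TI, D_TU, D_FI, D_FU, d_TI, d_TU, d_FI, d_FU, e_ver,
e_imp, a_ver, a_imp_true, a_imp_false, b`. `ConstraintSet` expresses any
equality structure; the empty set is the identity (24 free).

## Hierarchical (latent-trait) estimation

Participants are heterogeneous. Free parameters live on the probit scale:
`theta_pk = Phi(zeta_pk)`, `zeta_p ~ MVN(mu, Sigma)`. Priors: `mu_k ~ N(0,
1)` (so the implied group prior median is 0.5 per parameter), and a scaled
inverse-Wishart on the covariance, `Sigma = diag(xi) Q diag(xi)` with `Q ~
InvWishart(df = K + 1, scale = I)` and `xi_k ~ Uniform(0, 10)` — the standard
latent-trait defaults for this model family. Likelihood: product across
participants of the product-multinomial over the five item-type rows.

Sampling is Metropolis-within-Gibbs, vectorised across participants:

1. componentwise adaptive random-walk Metropolis on each `zeta_{.,k}`
   (Robbins–Monro adaptation to 44% acceptance during burn-in);
2. a joint translation move per parameter that shifts `mu_k` and all
   `zeta_{pk}` together (the centred parameterisation otherwise mixes
   slowly; this move targets 23% acceptance);
3. conjugate Gibbs draws for `mu` and for `Q`;
4. log-normal random-walk Metropolis on each `xi_k`.

Defaults mirror the reference analysis: 50,000 iterations, 20% burn-in,
thinning 10, two chains. Short runs used in the tests and the acceptance
script are noted below. Convergence is monitored with split R-hat (via
`arviz`) on the group-level probability-scale draws; the gate is R-hat <=
1.05, flagged in `PosteriorSamples.diagnostics` (non-fatal). Summaries are
posterior medians and equal-tailed credibility intervals (numpy's linear
quantile interpolation).

## Posterior-predictive checks

`T1` measures misfit of mean frequencies: for each retained draw,
`T1 = sum_cells (obs_mean - exp_mean)^2 / exp_mean` over the 25 item-type x
category cells (cells with zero expectation are skipped with a warning), with
expectations from that draw's participant-level parameters. `T2` measures
misfit of the across-participant covariance of the 25 frequency cells:
`T2 = sum_{k<=l} (obs_cov_kl - exp_cov_kl)^2 / (exp_sd_k exp_sd_l)`, where
the expected covariance combines the between-participant spread of expected
counts with the average within-participant multinomial covariance
(frequencies, not proportions). Each draw also generates a replicated
dataset from the same participant-level parameters; the posterior-predictive
p value is the fraction of draws with a replicated statistic at least as
large as the observed one.

## Contrasts

Contrasts are sampled differences of group-level parameters on the
probability scale (`Phi(mu)` per draw), summarised like any parameter; a
difference is credited when its 95% interval excludes zero. The standard
battery is Δd = d_TI − d_TU, Δd1 = d_TI − d_FI, Δd2 = d_TI − d_FU,
Δe = e_ver − e_imp, ΔD = D_TI − D_TU, ΔD1 = D_TI − D_FI, ΔD2 = D_TI − D_FU.
No multiplicity correction is applied across the battery (noted in the
report).

## Synthetic cohorts

The generator emulates the study design: 82 participants, 9 study statements
per source combination (36 studied), 18 distractors, 54 test items. The
default generating regime uses the observed group medians for joint
retrieval (`d_TI = .42, d_TU = .06, d_FI = .05, d_FU = .04`), strongly
separated dimension memory (`e_ver = .80, e_imp = .16`, consistent with the
observed dimension difference of ~.64), and neutral 0.5 for detection and
guessing; heterogeneity is sd 0.5 per parameter on the probit scale
(independent), a typical magnitude for individual differences in this
paradigm. Trial-level simulation attaches a Remember/Know tag to "old"
responses as an independent Bernoulli overlay (default rate 0.7, a typical
recollection share) — a data-coding device, not a modelled memory process.
Frequency- and trial-level simulation share one category stream per seed, so
collapsing trials under the Remember+Know rule reproduces the frequency
tables bit-for-bit.

What the generator does *not* emulate: statement content and plausibility,
counterbalancing versions, serial-position and buffer effects, response
times, and any cognitive structure in the Remember/Know judgment. Passing
recovery and calibration tests therefore shows that the estimation machinery
is correct and calibrated for data that follow the model, not that the model
is true of real participants.

## Response coding

Under `REMEMBER_ONLY` coding, an "old" response tagged Know is recoded as
"new" (default), keeping row totals fixed as the multinomial likelihood
requires; `drop_know_trials=True` excludes those trials instead, changing
row totals, and is provided because external analyses may have done either.
`REMEMBER_PLUS_KNOW` counts all old responses.

## Numerical choices and degenerate inputs

* Category probabilities are exact sums of products; rows sum to 1 to 1e-12
  by construction and test.
* `0 * log 0 := 0` in the multinomial log-likelihood; a positive count on a
  zero-probability category yields -inf (and proposal rejection in MCMC).
* `Phi` underflows to exactly 0/1 beyond |z| ~ 38; proposals reaching that
  region with conflicting data are rejected via the -inf rule.
* Positive semi-definite (including zero) group covariances are supported in
  the generator via the eigendecomposition sampling path.
* Equal-tailed intervals use numpy's default linear interpolation between
  order statistics.
* Seeds: every public sampler takes an integer seed; independent streams are
  split with `SeedSequence.spawn`.

## Problem sizes in tests and the acceptance script

The full 2 x 50,000-iteration defaults are intended for real analyses. The
package's own recovery and calibration runs use 82-participant cohorts with
chains of 1,200–8,000 iterations (20%–50% burn-in), sizes at which the
recovery and calibration properties reported by the test suite are stable;
the run log records the exact settings of every fit.

## Known limitations

* At 9 items per source, the near-zero joint-retrieval parameters and
  `e_imp` are weakly identified (joint retrieval trades off against strong
  independent retrieval); their recovery is assessed by interval coverage,
  not point error. With all parameters at 0.5 the d/e trade-off makes the
  d parameters nearly unidentified — an intrinsic property of the design,
  not an estimation failure.
* The sampler is random-walk based; posterior exploration at the study size
  needs a few thousand iterations per chain, and the R-hat gate should be
  respected before interpreting short runs.
* Calibrated 95% intervals exclude a true null ~5% of the time; joint
  statements over many contrasts inherit that arithmetic.
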