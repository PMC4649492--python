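# Methods

This package implements the complete statistical pipeline of a Bayesian
network meta-analysis (NMA) comparing five management options for knee
osteoarthritis — placebo, glucosamine, chondroitin, glucosamine plus
chondroitin, and celecoxib — from arm-level randomized-trial data through
effect sizes, MCMC fitting, SUCRA ranking, loop-inconsistency assessment,
classical pairwise meta-analysis with publication-bias testing, and
back-transformation to clinical scales. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
can and cannot demonstrate.

## Data model

Input is long-format arm-level data (one row per arm) with exactly one
outcome payload per analysis: continuous change scores (mean change, SD of
change, instrument maximum), binary event counts, or joint-space-width
narrowing in mm. Trials carry three sensitivity flags (methodological
quality, commercial support, baseline pain severity) that are *inputs*, not
computed quantities: risk-of-bias judgement is a manual process upstream of
this package. Arms are ordered by the fixed canonical treatment order
(placebo < glucosamine < chondroitin < combination < celecoxib); the
first-listed arm is each trial's baseline, and parsing is invariant to row
order. Trials reporting several doses of the same agent must arrive
pre-collapsed to one arm per treatment node — the schema deliberately
cannot represent dose arms.

## Effect measures

* **SMD** (pain, function): Hedges' g on change scores,
  g = J (m_b − m_a)/s_pooled with J = 1 − 3/(4(n_a+n_b−2) − 1) and
  variance (n_a+n_b)/(n_a n_b) + g²/(2(n_a+n_b)). The small-sample
  correction is the dominant convention in systematic reviews; negative
  values favour the second treatment. No pre/post imputation correlation is
  applied — the schema requires the SD of change directly.
* **MD** (joint-space width): millimetres, oriented so positive values mean
  less narrowing (structure preservation) on the second treatment.
* **log-OR** (safety): with a +0.5 continuity correction to all four cells
  only when some cell is zero. Double-zero trials are flagged
  non-informative and excluded from contrast-based pooling but retained by
  the binomial NMA likelihood, which needs no correction.
* **Multi-arm trials** yield a contrast vector against the baseline arm
  with the shared-baseline covariance approximation: off-diagonal terms are
  the baseline arm's own variance contribution (1/n for SMD, sd²/n for MD,
  1/e + 1/(n−e) for log-OR). The exact SMD covariance involves nuisance
  terms the data do not identify; this is the standard approximation.

## The NMA model

Basic parameters d_k are effects versus placebo; consistency defines all
other contrasts (d_bk = d_k − d_b), so a five-node network has 4 basic
parameters and 10 derived contrasts. Trial effects delta_i deviate from the
consistency means with one shared between-trial SD tau (homogeneous
variance). For an m-contrast trial the random-effects covariance is
exchangeable — tau² on the diagonal, tau²/2 off it — which is exactly the
joint form of the sequential conditional construction (arm k has
conditional variance tau²·k/(2(k−1)); the tests verify the equivalence
numerically).

Likelihood split: binary outcomes use the arm-based binomial-logit model
(events ~ Binomial(n, p), logit p = mu_i + delta_ik, baseline delta ≡ 0);
continuous and JSW outcomes use the contrast-based multivariate-normal
model with the known sampling covariance from the effect-measure stage.
Arm-level means on heterogeneous instruments cannot share one scale, which
is why the continuous model works on standardized contrasts.

Priors: all location parameters (d_k, mu_i) get Normal(0, 10⁴);
tau ~ Uniform(0, 2) on the SMD/MD scale and Uniform(0, 5) on the log-odds
scale — bounds wide enough to be vague for effects of the magnitudes seen
here while keeping the sampler in a numerically sane region.

## Sampling and diagnostics

The sampler is bespoke Metropolis-within-Gibbs, written here because the
hierarchical NMA model *is* the package's core. Conjugate normal nodes
(delta and d in the contrast model; d given deltas in the binomial model)
are Gibbs-updated from their exact conditionals; mu, the binomial deltas
and tau use random-walk Metropolis with Robbins–Monro step adaptation
(target acceptance 0.44 scalar / 0.3 blockwise) that is **frozen at the end
of burn-in**, so the retained draws come from a fixed kernel satisfying
detailed balance. With tau fixed at zero the contrast model collapses to
its exact conjugate posterior and draws are i.i.d. — this is the closed-form
oracle route used in testing.

Defaults are 3 chains × 50,000 iterations with the first 10,000 discarded.
Chains initialize deterministically but dispersed: d offset by
(c−1)·0.5 for chain c and tau at the 10/50/90% quantiles of its prior.
Runs are bitwise reproducible given the chain seeds (one PCG64 stream per
chain). Scaled-down iteration counts used in tests and the analysis
scripts are explicit configuration, chosen because this network reaches
split-chain PSRF < 1.05 well before the default length (the conjugate
normal model mixes essentially instantly; the binomial model needs a few
times longer, hence the larger counts in the safety analyses).

Summaries: league tables report the posterior median and the 2.5th/97.5th
percentiles of every ordered pair, computed from pooled post-burn-in
chains; OR-scale columns are exponentiated *after* percentile extraction.
Antisymmetry holds exactly per draw. Model fit is the posterior mean
residual deviance — binomial deviance summed over arms, or the Mahalanobis
form per trial for the normal likelihood — compared with the number of data
points (arms, respectively contrasts); a ratio near 1 indicates adequate
fit. Convergence is monitored by split-chain PSRF with a 1.05 flag.

## Ranking

Treatments are ranked per draw (lower effect is better for pain/function,
higher for JSW; placebo participates). SUCRA is the mean of the cumulative
rank probabilities over the first K−1 ranks, equivalently
(K − mean rank)/(K − 1); always-best gives 100%, always-worst 0%, and the
mean SUCRA across treatments is exactly 0.5. Exact ties (possible only in
degenerate fixtures — continuous posteriors are tie-free almost surely) are
broken by the canonical treatment order via a stable sort.

## Inconsistency

Loops are restricted to triangles — the network admits larger cycles, but
triangle loops are where direct and indirect evidence meet most simply, and
they cover every closed comparison of interest here. Direct edge estimates
come from DerSimonian–Laird random-effects pooling of the per-trial
contrasts; the indirect estimate is the signed sum along the other two
edges with variances summing. IF = |direct − indirect| with a normal-theory
95% CI; the assessment is invariant to which edge is designated the target.
On the log-odds scale IF exponentiates to the ratio of odds ratios
(RoR ≥ 1 by orientation); for SMD/MD the IF stays on the original scale,
since a "ratio of odds ratios" is undefined there. Flagging is by the CI
excluding zero only — no numeric "moderate inconsistency" criterion is
imposed.

## Pairwise meta-analysis and publication bias

DerSimonian–Laird is the classical random-effects estimator (the default of
the era's standard software): Q from fixed-effect weights, the moment
estimator for tau² truncated at zero, then inverse-variance pooling with
weights 1/(v_i + tau²). I² = max(0, (Q − df)/Q)·100; both Q's p-value and
I² are reported and the flagging rule is left to the caller, because the
two can disagree near the boundary. Begg's rank-correlation test uses
tie-corrected Kendall's tau between variance-standardized deviates and
variances; the two-sided p-value is exact (full permutation enumeration)
for k ≤ 8 and the normal approximation beyond — k = 8 balances fidelity
against the factorial cost. A caveat the synthetic runs make visible: under
strong between-trial heterogeneity the deviates are standardized by the
within-trial variance only, so Begg's test rejects more often than nominal
even without bias; its calibration test therefore runs at tau = 0.

## Clinical translation

Pooled pain SMDs are back-transformed to cm on a 0–10 VAS by multiplying
point estimate and CI bounds by the median pooled SD of 2.5 cm; function
SMDs by 2.1 units to the standardized 0–10 WOMAC function scale. The
transformation is linear and applied bound-wise. Absolute within-group
changes are rescaled to the 0–10 scale (×10/scale_max) and pooled across
trials with the same DL machinery (v_i = rescaled sd²/n); a pooled change
of 2.0 points or more in the improving (negative) direction counts as
clinically significant — the boundary is inclusive, the flag uses the point
estimate (the CI is reported alongside), and worsening changes never
qualify.

## Synthetic data: what it emulates and what it does not

The generator is the package's study-conditions statement. The default
scenario is a 54-trial, five-node connected network of 16,725 patients with
a placebo hub, head-to-head edges closing the
celecoxib/glucosamine/chondroitin and celecoxib/glucosamine/combination
loops, two 3-arm trials, one 4-arm and one 5-arm trial. True pain SMDs are
(−0.20, −0.18, −0.27, −0.27) for glucosamine, chondroitin, combination and
celecoxib versus placebo with tau = 0.2 — the SMDs implied by
back-transformed differences of about −0.5, −0.45 and −0.68 cm at a pooled
SD of 2.5 cm. JSW truths are 0.18/0.15 mm for glucosamine/chondroitin;
adverse-event truths are the log odds ratios of the corresponding safety
contrasts. Defaults chosen where no source value exists: placebo-arm change
−1.5 points on the 0–10 scale (a typical contextual response in knee-OA
trials, placing effective treatments near the 2-point clinical threshold),
change-score SD 2.5, AE risk 0.15 per baseline arm with SD 0.3 on the
logit, JSW narrowing 0.30 ± 0.45 mm, 13/54 trials flagged poor quality,
43/54 commercially supported, and 60/20/20% yes/no/unknown baseline-severity
flags. Every fifth trial reports on a 0–100 instrument to exercise
rescaling.

What passing tests show: the estimators are calibrated, the sampler matches
conjugate closed forms, 95% credible intervals attain ≈94% coverage of the
generating truth at scaled-down MCMC settings, and the residual-deviance
criterion sits near its expected value under a well-specified model. What
they do not show: robustness to anything the generator omits — missing
data, dropout, dose heterogeneity, outcome-scale hierarchies, correlated
flags, small-study effects, or genuine inconsistency. Real extractions
violate several of these at once, so the green suite certifies the
machinery, not any clinical conclusion. One consequence of the stated
truth worth flagging: with celecoxib and the combination tied at −0.27 and
glucosamine only 0.07 away, the identity of the top-two SUCRA pair is
genuinely uncertain at this sample size (it matches the truth ordering in
roughly half of replicates); the recovery tests therefore assert the stable
features — placebo last, and the truly superior treatments averaging above
the inferior ones — rather than the coin-flip event.

## Problem sizes in packaged runs

The analysis scripts fit 3 chains of 12,000 iterations (2,000 burn-in) for
the contrast-normal model and 25,000 (5,000) for the binomial model; the
recovery study runs 50 replicates at 3 × 5,000 (1,000). These sizes give
PSRF < 1.05 and Monte Carlo error well below the reported precision on this
network, and are the package's choice for interactive reproducibility; the
full-length default remains available via configuration.

## Known limitations

* No node-splitting or design-by-treatment inconsistency model; loop
  assessment is Bucher triangles only.
* No meta-regression, informative priors, Egger regression or
  trim-and-fill.
* The binomial sampler's tau mixes noticeably more slowly than the rest;
  very sparse safety outcomes (many zero cells) will need longer chains.
* The clinical-significance flag uses the point estimate; a CI-based rule
  is a caller-side decision.
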