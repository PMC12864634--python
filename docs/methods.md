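# Methods

## Data model

Each study contributes a log odds ratio y and standard error σ. From a 2×2
table (a = treatment events, b = treatment non-events, c = control events,
d = control non-events) these are the Woolf estimates
y = ln(ad/bc), σ = √(1/a + 1/b + 1/c + 1/d). A zero cell triggers the
Haldane–Anscombe correction — 0.5 added to all four cells — only when a
zero is present; with the correction disabled a zero cell is an error, and
an arm with neither events nor non-events is always an error. When a study
is entered both as counts and as (y, σ), the pair must agree with the
counts-derived value to 1e-9 or the input is rejected: silent inconsistency
between two encodings of the same trial is the failure mode this guards.

Published 95% CIs are converted to standard errors as
σ = (upper − lower)/(2·1.96) on the log scale, the usual extraction route
when primary tables report intervals rather than variances. The 1.96 is
fixed, not a configurable quantile, so extraction is reproducible.

Chronological ordering uses the `year`/`order_key` column ascending with
ties broken by input order, making sequential analyses deterministic.

## Frequentist track

Fixed-effect: μ̂ = Σwᵢyᵢ/Σwᵢ with wᵢ = 1/σᵢ². Heterogeneity:
Q = Σwᵢ(yᵢ − μ̂_FE)², I² = max(0, (Q − (K−1))/Q)·100. Between-study
variance τ² by DerSimonian–Laird moments or by REML; REML is the default
because it is the default of the standard random-effects software this
package is meant to be compared against, and DL remains available for
textbook cross-checks. REML is solved by the standard fixed-point
iteration on the profiled restricted likelihood (tolerance 1e-10 on
successive τ² iterates, 200-iteration cap, boundary value 0 kept whenever
it has higher restricted likelihood). Random-effects weights are
wᵢ* = 1/(σᵢ² + τ²). All intervals are Wald with the fixed 1.96 quantile —
no Knapp–Hartung adjustment — and p-values are two-sided normal tails.

A single-study dataset degrades an RE request to the FE answer with a
warning rather than an error, because a cumulative analysis must start at
K = 1; Q and I² are reported as NaN there and the model actually used is
recorded per step.

`pseudo_likelihood_ratio(p) = (1 − p)/p` is included purely as the
didactic comparator sometimes quoted against Bayes factors under the
(false) premise that H₁ is the complement of H₀; it is documented as such
and plays no inferential role.

## Bayesian track

Model space: {FE0, FE1, RE0, RE1}, fixed/random effects crossed with
null/alternative, uniform prior probability ¼ each by default. The effect
prior is a two-sided, untruncated Cauchy(0, 0.707) on the pooled log OR;
the heterogeneity prior is an inverse gamma with shape 1 and scale 0.15
placed on the between-study **standard deviation** τ, not the variance —
the convention of the Bayesian model-averaging framework these parameter
values come from. Because "(1, 0.15)" is ambiguous across
parameterizations, `PriorSpec` names both parameters explicitly
(`ig_shape`, `ig_scale`; density ∝ τ^(−α−1)·exp(−β/τ)).

### Marginal likelihoods

m(y|FE0) is closed-form. The others are integrals of the normal likelihood
against the priors. Each is computed after the probability-integral change
of variable u = F(parameter): the integrand becomes the likelihood
evaluated at the prior quantile function on (0, 1), so the heavy Cauchy
tails and the unbounded τ axis are handled by the substitution itself —
nothing is truncated. Gauss–Legendre rules (201 nodes per axis, doubled to
401, 801, 1601 until successive values differ by < 1e-6 in log units) do
the integration; RE1 uses the tensor product of the two axes. All
accumulation is log-sum-exp. Failure to converge before the node cap
attaches a diagnostic and raises a `QuadratureWarning`, never a silent
result. On K ≤ 3 datasets the quadrature values agree with brute-force
Riemann/grid references to well below 1e-5 log units (tested).

The likelihood is evaluated in sufficient-statistic form: for fixed τ,
log L(μ, τ) is a quadratic in μ built from S₀ = Σ1/vᵢ, S₁ = Σyᵢ/vᵢ,
S₂ = Σyᵢ²/vᵢ with vᵢ = σᵢ² + τ². This makes the 2-D quadrature O(n_τ·K +
n_τ·n_μ) instead of O(n_τ·n_μ·K) and keeps the Monte-Carlo studies cheap
without any approximation.

### Bayes factors and model averaging

BF₁₀ is the prior-weighted marginal likelihood of the alternative models
over the null models; BF_rf the RE models over the FE models. Posterior
model probabilities are proportional to prior × marginal. Interpretation
helpers fold BF₁₀ < 1 into "H₀ is 1/BF₁₀ times more likely" language; no
evidential threshold is hard-coded anywhere — what counts as convincing is
deliberately left to the reader.

### Posterior of μ and credible intervals

The reported posterior averages the two alternative models:
p(μ|y, H₁) = w·p(μ|y, FE1) + (1−w)·p(μ|y, RE1) with w the posterior
probability of FE1 renormalized among {FE1, RE1}. Averaging over all four
models (a spike at 0 with the null models' posterior mass) is available
via `include_null=True`; H₁-only averaging is the primary output because
the headline credible interval describes the effect *given that there is
one*. The density is tabulated on a grid spanning at least
μ̂_FE ± 6·max(maxᵢσᵢ, pooled σ), with a nested finer grid over
μ̂_FE ± 12·pooled σ so that one very imprecise study cannot starve
resolution where the mass sits; if trapezoid mass falls below 1 − 1e-6 the
span doubles automatically (error after five attempts). Intervals are 95%
equal-tailed from the numeric CDF — matching the symmetric look of
standard reports; HPD intervals are not provided.

### Shrinkage

Under RE1, θᵢ | μ, τ, y is normal with mean (1−Bᵢ)yᵢ + Bᵢμ and variance
σᵢ²(1−Bᵢ), Bᵢ = σᵢ²/(σᵢ² + τ²). The reported per-study posterior mixes
this conditional over the joint quadrature posterior of (μ, τ); CrIs come
from the normal-mixture CDF inverted by root-finding. τ is floored at
1e-8 purely to keep the conditional variance positive at the quadrature
node nearest the τ → 0 boundary.

### Savage–Dickey diagnostic

For the nested FE pair, BF₀₁ equals the posterior density of μ at 0 over
the prior density at 0. `savage_dickey_bf_fe` computes the posterior
density on a dense grid with its own normalizer, so agreement with
exp(log m_FE0 − log m_FE1) is a genuine cross-check of the quadrature
marginals (it agrees to ~1e-10 relative in the tests); it is a diagnostic,
not part of the model-averaged output.

## Sequential track

Each step k is a full batch analysis of studies 1..k under the same
initial priors. This is mathematically identical to carrying the previous
posterior forward as the prior — the marginal likelihood telescopes as
m(y₁..k) = m(y₁..k₋₁)·p(yₖ|y₁..k₋₁) — and the per-model predictive
factors p(yₖ|y₁..k₋₁) are exposed directly (`sequential_decomposition`,
with m(∅) = 1), so the test suite proves the identity rather than assuming
it. The ordering used is always recorded in the output because cumulative
conclusions are sensitive to it. No alpha-spending or stopping boundaries
are applied across looks.

## Synthetic data

Two modes:

* **normal-effects** — exactly the likelihood the Bayesian models assume:
  θᵢ ~ N(μ, τ²), σᵢ ~ Uniform(0.2, 0.6) by default, yᵢ ~ N(θᵢ, σᵢ²).
  Used wherever a test needs model-matched truth (coverage, type-I error,
  consistency), since any discrepancy is then attributable to the
  implementation, not model misfit.
* **binomial-trials** — two-arm binary trials: per-arm sizes uniform in
  100–300, control events ~ Binomial(n, 0.10), treatment events through
  expit(logit(p_ctrl) + θᵢ), effect sizes via the corrected Woolf log OR.
  Defaults emulate small surgical-prevention RCT portfolios (six trials,
  ~10% control-arm event risk, protective μ = −0.5, τ = 0.2): realistic
  enough to exercise zero-cell handling and the full CSV pipeline.

One top-level seed feeds a `SeedSequence.spawn` substream per replicate,
so single replicates are reproducible in isolation. What the generator
does **not** emulate: publication bias or small-study effects, binary-data
likelihood misspecification beyond the binomial mode (the analysis model
is always the normal approximation), clinical heterogeneity of
populations, or time-to-event outcomes. Passing simulation tests therefore
demonstrates numerical and statistical correctness of the machinery under
its own assumptions, not robustness of conclusions on arbitrary real data.

## Monte-Carlo problem sizes

Operating characteristics are checked at: type-I error of the RE test —
2000 replicates of K = 10 null studies (accepted band 0.03–0.07); CrI
coverage — 500 replicates of K = 50 at μ = −0.5, τ = 0.2 (within 3
binomial SEs of 0.95, posterior-mean bias < 0.02); sequential evidence
growth — 200 replicates of 6 studies at a common μ = −0.5 (median BF₁₀
strictly increasing in k). These sizes keep Monte-Carlo error comfortably
inside the accepted bands while the whole suite remains a few minutes of
single-CPU work.

## Known limitations and open choices

* The analysis likelihood is the standard normal approximation to the log
  OR; very small trials or rare events strain it, and the continuity
  correction adds its own small bias for zero-cell tables.
* The inverse-gamma heterogeneity prior is proper but informative in its
  tail; with one or two studies the τ posterior is essentially the prior.
* Quadrature is deterministic and seed-free but assumes the posterior is
  not pathologically multimodal in (μ, τ); for meta-analytic normal
  likelihoods it is not.
* MCMC is deliberately not the engine; the package's credible intervals
  and Bayes factors are reproducible bit-for-bit across runs.
* Report-layer rounding is 3 decimals (4 for p-values); JSON always
  carries full precision.
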