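# Methods

This note records the statistical models implemented in `rectalresponse`,
the conventions chosen where several were defensible, what the synthetic
cohorts do and do not emulate, and the package's known limitations.

## Variant filtering and tumor mutation burden

A variant is retained when depth ≥ 30 **and** allele fraction ≥ 0.1
(exclusion is strict `<`, so boundary values survive) and its MAF
classification is in the nonsynonymous coding set {Missense_Mutation,
Nonsense_Mutation, Nonstop_Mutation, Frame_Shift_Del, Frame_Shift_Ins,
In_Frame_Del, In_Frame_Ins, Splice_Site, Translation_Start_Site}. Records
missing depth or allele fraction are retained and tallied (public panel
exports often lack these columns); `FilterConfig(strict_missing=True)`
drops them instead.

TMB is the retained-variant count divided by the coding footprint in
megabases. The footprint is data-set specific — 38 Mb is a typical whole
exome, ~1.5 Mb a typical targeted panel — and must be chosen by the user;
nothing in a MAF file identifies it reliably.

## Weighted comparison conventions

Weights are treated as **reliability weights**: weighted mean
x̄ = Σwx/Σw, variance s² = Σw(x−x̄)² · W/(W²−Σw²) with W = Σw, and effective
sample size n_eff = W²/Σw². The weighted t-test uses
t = (x̄₁−x̄₀)/√(s₁²/n₁+s₀²/n₀) with Welch–Satterthwaite degrees of freedom on
the effective sizes, and reduces exactly to the unweighted Welch test under
unit weights (asserted to 1e-10 in tests). Standardized differences are
100·|x̄₁−x̄₀|/√((s₁²+s₀²)/2), with Bernoulli variance p(1−p) for binary
covariates; both conventions are scale-invariant in the weights.

## Propensity balancing

The propensity of complete response is fit by logistic regression
(continuous covariates standardized internally; multi-level categoricals
expanded to indicator columns). Matching weights are
min(e,1−e)/e for CR and min(e,1−e)/(1−e) for ICR, with scores clipped to
[1e−6, 1−1e−6]. Rows with any missing covariate are excluded
(complete-case) with a logged count.

The balance-revision loop is this package's concrete reading of iterative
"balance checking": after each fit, if any weighted standardized difference
is ≥ the threshold (default 10%), the squared term of the worst-balanced
continuous covariate is appended; once its square exists, its interaction
with the next-worst covariate; squares of remaining continuous covariates
are the final fallback. The augmentation path is deterministic and recorded
per iteration. Non-convergence after `max_iter` returns a flagged result
with a warning — never a silent success.

## Exact tests and multiplicity

The two-sided Fisher p-value sums hypergeometric probabilities (margins
fixed) of all tables at most as probable as the one observed, with a 1e−7
relative tolerance guarding floating-point ties; the implementation is
checked against rational-arithmetic enumeration on random tables up to
N = 60. The reported odds ratio is ad/bc with a Haldane +0.5 added to every
cell **only when a cell is zero and only for the estimate** — the p-value is
always exact. The chi-squared test applies the Yates continuity correction
(|O−E| reduced by 0.5, floored at zero), df = 1.

Pairwise co-occurrence / exclusivity calls use raw p < 0.05 by default,
mirroring the star-marking convention of maftools-style interaction plots;
a Benjamini–Hochberg mode (`adjust=True`) is available and is used by the
closed-loop recovery benchmark to keep decoy pairs out of the count
feature. Because the exact test is discrete it is conservative: under
independence at cohort sizes of 200–300 the realized false-positive rate is
≈ 0.03–0.045 at nominal 0.05. Candidate genes for the network default to
those above 5% mutation frequency, capped at the 25 most frequent.

## Logistic fitting and model selection

`statcore.logistic_mle` is a plain IRLS Newton iteration on the Bernoulli
likelihood: convergence when max |score| < 1e−8 or no coefficient moves by
more than 1e−10; standard errors from the inverse observed information.
Quasi-complete separation is flagged heuristically (any |β| > 15 on a
standardized column → non-converged + warning). Rank-deficient designs
raise an error naming the collinear columns; factor levels unobserved in
the data (e.g. no sample with ≥ 3 co-occurring pairs) are dropped from the
design with a logged warning rather than silently breaking the fit.

The response model uses reference coding (stage 2, count category "0",
indicator "no mutation" as references). Both count functional forms —
continuous pair count and the 0 / 1–2 / 3-or-more category — are fit;
selection takes the lowest AIC, breaking near-ties (ΔAIC < 1e−6) by the
higher Tjur R², and warns explicitly when the two criteria disagree.
Odds-ratio intervals are Wald (exp(β ± 1.96·SE)); profile-likelihood
intervals, which are asymmetric for sparse categories, are not implemented,
and Wald intervals for rare categories should be read with that in mind.
The co-occurrence block is additionally tested by a likelihood-ratio test
against the nested model without it. Classification metrics are computed on
the training cohort at a configurable probability threshold (default 0.5);
because screening and fitting share the cohort, these metrics are
optimistic by construction.

## Synthetic cohorts

The generator's defaults define the package's reference study conditions: a
364-patient cohort (104 CR / 260 ICR); age ~ N(60, 10) years,
BMI ~ N(27, 5), 35% female, tumor size lognormal (median 4.6 cm, log-sd
0.32), 60% stage 3. CR assignment is confounded: samples are selected into
the CR group with probability proportional to exp(logit) of a covariate
score (Plackett–Luce sampling preserves the exact group sizes), so the
naive CR−ICR TMB contrast is biased — the property the balancing stage must
undo. With the default coefficients the realized tumor-size medians differ
by ≈ 0.3 cm between groups, on the scale reported for real cohorts.

Mutation totals are panel-like (13 CR / 9 ICR expected mutations per sample
over a 1.5 Mb footprint) since targeted-panel data dominate the real
cohorts this emulates. DNA-repair genes (MSH3, MLH1, PMS1, BRCA1, BARD1,
POLD1, POLE) are planted CR-enriched; common drivers (APC, TP53, KRAS,
PIK3CA, FBXW7) ICR-enriched. Planted co-occurring pairs use a shared latent
Bernoulli factor: X = L∨A, Y = L∨B with the firing probability q solved by
root finding so the pair's odds ratio hits the requested target while the
marginal frequencies are preserved exactly — invertible, so recovery tests
can check against truth. Each MAF includes a configurable fraction
(default 20%) of decoy rows with sub-threshold depth or allele fraction
that the filter stage must remove exactly.

Closed-loop mode regenerates the response label from a known logistic model
(defaults at the scale of a published rectal-cancer response model: tumor
size log-OR log 0.79, network-gene log 2.57, 1–2 pairs log 1.57, ≥3 pairs
log 8.47), making the full screen → features → fit pipeline testable
against planted coefficients.

What the generator does **not** emulate: mutational signatures, real gene
lengths or hotspots (each gene sits on its own pseudo-contig), copy-number
events, panel/exome capture heterogeneity across sub-cohorts, missing
clinical data patterns, and correlation between TMB and MSI status. Passing
tests therefore demonstrate correctness of the statistical machinery under
the generative model, not robustness to every artifact of real registry
data.

## Recovery benchmark scale

The end-to-end coefficient-recovery benchmark runs on 2000-patient
closed-loop cohorts. At the 364-patient reference scale the limiting factor
is the bivariate p < 0.1 pair screen itself: it misses one or two of the
eight planted pairs per replicate, the per-sample count feature is then
mis-measured, and AIC tends to prefer the continuous count form even though
the generative effect is a step at three pairs (the Wald interval for the
"3 or more" category still covers the truth in ≥ 90% of replicates because
it is wide at that n). At n = 2000 the screen is faithful, model selection
prefers the categorical form essentially always, and coverage matches the
oracle that is given the true features. This mirrors the familiar
two-stage-inference caveat: screened features are measured with error that
vanishes only as screening power approaches one.

## Known limitations

- Wald, not profile, confidence intervals (see above).
- The weighted t-test's degrees of freedom use effective sample sizes; no
  design-based (survey) variance estimator is provided.
- MutSig2CV-style background-mutation-rate q-values are consumed, not
  produced; group-specific classification requires an external caller's
  output.
- No train/test split by default: metrics reproduce the training-data
  convention and overstate out-of-sample performance.
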