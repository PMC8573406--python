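# Methods

## The modulator model

The scan treats a miRNA as a candidate pathway modulator when the genes of
one pathway concentrate at an extreme of the miRNA's mRNA association
ranking. Three assumptions matter:

1. **Linear purity confounding.** Bulk expression of both miRNAs and mRNAs
   is assumed to depend on tumor purity linearly; the first-order partial
   correlation removes exactly this component. Non-linear purity effects,
   or confounders other than purity (batch, library size), are not
   removed.
2. **Per-gene association is informative.** The rank index
   `−ln(p)·sign(PCC)` is a monotone transform of the association evidence;
   its normal-approximation p-value (the `z = PCC·√(n−3)/√(1−PCC²)`
   statistic) is adequate for ranking even at modest n, where its absolute
   calibration is rough. A Fisher-z variant (`atanh(PCC)·√(n−3)`) is
   available via `p_method="fisher"` for sensitivity analysis.
3. **Gene-label exchangeability under the null.** The permutation null
   redraws the gene set as a size-matched random subset of the ranked
   list. This is honest only when set genes are not much more
   inter-correlated than random genes; strongly co-expressed sets inflate
   the test (see Limitations).

The permutation p is one-sided on the sign of the observed ES and is
normalized over the matching-sign permutations,
`p = (1 + #{matching sign, |ES_perm| ≥ |ES_obs|}) / (1 + #matching)`,
which keeps null p-values approximately uniform; normalizing by the total
permutation count instead roughly doubles the null rejection rate, which
the test suite checks against. `TES = (1 − 2p)·sign(ES)` uses the
BH-adjusted p by default (`tes_p="raw"` switches). A consequence of the
formula worth knowing: a p-value near 1 yields |TES| near 1 with the
*opposite* sign of the ES. Such miRNAs can never be flagged — the FDR
clause blocks them — but a TES magnitude alone is not evidence.

Flagging uses |TES| > 0.995 with FDR < 0.05, both strict. Because the
adjusted p drives TES, |TES| > 0.995 already implies adjusted p < 0.0025;
with m miRNAs tested and k true signals at the permutation floor, the
floor must satisfy `floor·m/k < 0.0025`, so the default 10,000
permutations are not a luxury — at 500 permutations the threshold is
unreachable and every scan returns zero flags.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_perm` | 10,000 | gene-label permutations per miRNA |
| `weight` | 1.0 | KS weight exponent on \|rank index\| |
| `min_set_size` | 5 | minimum mapped set genes after intersection |
| `tes_threshold` | 0.995 | flag requires \|TES\| strictly above |
| `fdr_threshold` | 0.05 | flag requires BH-FDR strictly below |
| `max_zero_fraction` | 0.5 | zero-fraction filter (strict >) |
| `p_screen` | 0.1 | univariate Cox screen, unadjusted p |
| `min_prop` | 0.1 | minimum group fraction for the cutoff search |
| `alpha` (ssGSEA) | 0.25 | rank-weight exponent |

Numerical guards: p-values floored at 1e-300, |PCC| clamped to 1−1e-12
(so the rank index stays finite), ties broken lexicographically by id
everywhere a sort occurs, and an all-zero-weight hit set falls back to
equal mass per hit. Quantile normalization assigns tied values the mean of
the reference quantiles their block spans; it is exactly idempotent on
tie-free data but not in the presence of ties.

## Survival stack

Cox fits use lifelines (Efron ties). Fits that diverge (monotone
likelihood / complete separation, detected from the solver's delta-norm
warning or non-finite Wald statistics) are returned with
`converged=False` and no hazard ratio rather than silently huge
coefficients. The L1 path is glmnet-style coordinate descent
(scikit-survival Coxnet, objective `−logPL/n + λ‖β‖₁`); because that
solver stops its path early once the fit saturates, the path helper
refits the uncovered tail so every requested λ is actually solved — the
unpenalized limit then agrees with lifelines to < 1e-4. The LOOCV
deviance of subject *i* is `−2·[logPL_full(β₋ᵢ) − logPL₋ᵢ(β₋ᵢ)]`
(Verweij & van Houwelingen) with a Breslow log partial likelihood;
λ* minimizes the mean, and the signature keeps the penalized nonzero
coefficients at λ*. `lambda_max = max|∇logPL(0)|/n` gives the analytic
all-zero point of the path and anchors the default grid
(50 log-spaced values down to `0.01·lambda_max`).

The maximally selected cutoff maximizes the two-group log-rank statistic
over observed scores with both groups ≥ 10% of the cohort, lower value on
ties. The subsequent log-rank p on the same data is optimistic; it is
reported, deliberately uncorrected, and the docstring says so. The
candidate screen likewise uses unadjusted p < 0.1 by design: with small
cohorts, multiplicity correction at this stage removes real prognostic
signal faster than it removes noise, and the cross-cohort
direction-concordance requirement does the de-noising instead.

Time-dependent AUC is cumulative/dynamic with IPCW (KM censoring
estimator); Harrell's C uses the censored pair counts with a
normal-approximation CI (`SE = √(C(1−C)/pairs)`) — adequate for
comparing models, crude for inference near C = 1. Decision curves convert
scores to horizon event probabilities through a Cox Breslow baseline and
estimate TP/FP fractions KM-style inside the treated group.

## What the simulator emulates — and what it does not

`simulate_cohort` generates: purity ~ Beta(5,2); miRNA = baseline +
δ·purity + N(0,1) with δ ~ N(0, 0.5²); one pathway set of 40 genes
partitioned among 5 planted modulators, each gene coupled to exactly one
modulator at slope ±0.8 (one sign per modulator; per-gene random signs
would make the planted direction, and hence sign agreement, undefined);
pathway genes carry a sign-coherent purity loading, the way stromal and
immune programs track malignant-cell fraction — exactly the confounding
the partial correlation exists to remove, and the test suite shows that
replacing purity with a constant inflates null couplings. Survival is
exponential proportional hazards on the z-scored planted prognostic
miRNAs (log-HR +0.8 and −0.8 per SD for two of the modulators; baseline
hazard 0.05/month), with uniform censoring whose upper bound is bisected
so the realized censored fraction hits the requested 30% ± 5%. A
`structure_seed` fixes the planted structure across independently drawn
cohorts, which is what cross-cohort discovery/validation needs.

Not emulated: real library-size artifacts, batch effects, heavy-tailed
counts, correlated miRNA families, multi-pathway crosstalk, or realistic
censoring mechanisms. Passing tests therefore show the algorithms are
implemented correctly and calibrated under their own assumptions — not
that the biological discovery rate on real cohorts will match.

## Problem sizes used in the checks

The bound check runs 200 null cohorts of 30 samples at 500 permutations
(~1 minute); recovery runs seeds 1–10 at the default cohort size with
10,000 permutations (~2 minutes); null calibration uses 20 cohorts of
1,000 permutation p-values and 500 null pathway Cox fits. These sizes
keep the whole suite a few minutes long while leaving the binomial
acceptance bands (±3·SE) tight enough to catch a miscalibrated test.

## Known limitations

- Gene-label permutation understates the null spread for strongly
  co-expressed gene sets; the simulator's block structure already shows a
  mild excess false-positive rate (≈3–4% at the flag level under the
  default conditions, within the acceptance band but not at the nominal
  5%·FDR level a fully exchangeable null would give).
- The packaged 28 immune-cell GMT is a synthetic stand-in (marker lists
  are illustrative); substitute a published signature collection for real
  analyses. The 18-gene TIS list is the published panel.
- No competing risks, no optimism correction for the selected cutoff, no
  incident/dynamic AUC, no nomogram — all deliberately out of scope.
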