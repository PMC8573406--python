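# pathmir

Identify microRNAs that modulate a pathway from paired bulk miRNA/mRNA
expression, and turn them into a validated prognostic risk signature.

Bulk tumor expression mixes malignant and stromal/immune cells, so naive
miRNA–mRNA correlations are confounded by tumor purity. `pathmir`
implements a three-step scan that deals with this directly, plus the full
downstream survival-signature workflow, and a synthetic-cohort simulator
with planted ground truth so every stage can be tested end to end without
any external data.

## The method

**Step 1 — purity-adjusted ranking.** For miRNA *i* and mRNA *j* with
purity vector *p*, the first-order partial correlation removes the linear
purity effect:

    PCC_ij = (R_mim − R_mip·R_mp) / (√(1−R_mip²)·√(1−R_mp²))

with `R` the pairwise Pearson coefficients. Its normal-approximation
p-value, `P_ij = 2·Φ(−|PCC_ij·√(n−3)/√(1−PCC_ij²)|)`, gives a signed rank
index `RI_ij = −ln(P_ij)·sign(PCC_ij)`; sorting all mRNAs by descending RI
puts positively coupled genes at the top and negatively coupled ones at the
bottom.

**Step 2 — permutation GSEA.** The pathway gene set is tested against the
ranked list with the weighted Kolmogorov–Smirnov enrichment score (ES).
Significance comes from size-matched random gene sets: a one-sided
permutation p on the sign of the observed ES, normalized over the
matching-sign permutations, then Benjamini–Hochberg corrected across
miRNAs.

**Step 3 — TES.** Significance and direction collapse into a single score

    TES_i = (1 − 2·P_i) · sign(ES_i)   ∈ [−1, 1]

miRNAs with |TES| > 0.995 and FDR < 0.05 are flagged as pathway-derived
modulators.

**Signature.** Modulator miRNAs are z-scored per cohort and screened by
univariate Cox in two cohorts (unadjusted p < 0.1, concordant HR
direction). An L1-penalized Cox model — penalty chosen by leave-one-out
cross-validated partial likelihood deviance (Verweij–van Houwelingen) —
yields a sparse linear risk score `Σ expressionᵢ·coefficientᵢ`. Samples
split at the maximally selected log-rank cutoff; evaluation covers KM /
log-rank, covariate-adjusted Cox, IPCW time-dependent AUC, Harrell's C,
calibration and decision curves, plus ssGSEA pathway/immune activity and
the 18-gene T-cell-inflamed signature.

## Worked example

```python
from pathmir import simulate_cohort, modulator_scan, evaluate_recovery

cohort = simulate_cohort(seed=1)            # 100 samples, 50 miRNAs, 5 planted
records, _ = modulator_scan(
    cohort.mirna, cohort.mrna, cohort.purity,
    cohort.gene_sets["PATHWAY_PLANTED"], n_perm=10_000, seed=1)
print(evaluate_recovery(cohort, records))
```

Running `python examples/01_simulate_and_scan.py` prints:

```
miRNA           ES    p_perm       FDR      TES  flagged
mir-002     -0.907  1.52e-04  1.51e-03  -0.9970  True
mir-022      0.897  1.35e-04  1.51e-03   0.9970  True
mir-025     -0.885  1.26e-04  1.51e-03  -0.9970  True
mir-036      0.657  1.81e-04  1.51e-03   0.9970  True
mir-037     -0.905  1.29e-04  1.51e-03  -0.9970  True
mir-047      0.873  1.30e-04  1.51e-03   0.9970  True
...
planted modulators : ['mir-002', 'mir-022', 'mir-025', 'mir-037', 'mir-047']
sensitivity        : 1.00
false positive rate: 0.022
sign agreement     : 1.00
```

All five planted modulators are flagged with the correct coupling
direction (negative TES = the miRNA suppresses the pathway genes); one of
45 null miRNAs is a false positive. `examples/03_signature_pipeline.py`
continues into the signature stage and reports, for an independent
validation cohort, `HR(high vs low) = 5.72, log-rank p = 2.2e-09,
C-index = 0.741` — the frozen discovery coefficients rank survival in new
data.

The other examples cover preprocessing (`02`), pathway-activity screening
and TIS (`04`) and the clinical evaluation suite (`05`). A thin CLI wraps
the same calls:

```bash
pathmir simulate --seed 1 --out cohort/
pathmir discover --mirna cohort/mirna.tsv --mrna cohort/mrna.tsv \
    --purity cohort/purity.csv --gmt cohort/gene_sets.gmt \
    --set-name PATHWAY_PLANTED --seed 1 --out modulators.tsv
```

## Layout

- `src/pathmir/iokit.py` — matrices, gene sets, survival/purity tables, preprocessing
- `src/pathmir/modulators.py` — the three-step modulator scan
- `src/pathmir/enrichment.py` — ssGSEA, pathway screen, TIS
- `src/pathmir/survival.py` — Cox screening, L1-Cox/LOOCV, cutoff, evaluation
- `src/pathmir/simdata.py` — synthetic cohorts with planted truth
- `src/pathmir/pipeline.py`, `cli.py` — orchestration and the `pathmir` command
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
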