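"""Simulate a paired miRNA/mRNA cohort and scan for pathway-coupled miRNAs.

The simulator plants five modulator miRNAs whose expression drives a 40-gene
pathway set (with purity confounding); the scan ranks every mRNA per miRNA
by purity-adjusted partial correlation, tests the set by permutation GSEA,
and flags miRNAs with |TES| > 0.995 and FDR < 0.05.
"""

from pathmir import evaluate_recovery, modulator_scan, simulate_cohort

cohort = simulate_cohort(seed=1)
records, skipped = modulator_scan(
    cohort.mirna, cohort.mrna, cohort.purity,
    cohort.gene_sets["PATHWAY_PLANTED"], n_perm=10_000, seed=1,
)

print(f"{'miRNA':<10} {'ES':>7} {'p_perm':>9} {'FDR':>9} {'TES':>8}  flagged")
for r in sorted(records, key=lambda r: -abs(r.tes))[:8]:
    print(f"{r.mirna_id:<10} {r.result.es:>7.3f} {r.result.p_raw:>9.2e} "
          f"{r.result.fdr:>9.2e} {r.tes:>8.4f}  {r.is_modulator}")

report = evaluate_recovery(cohort, records)
print(f"\nplanted modulators : {cohort.truth['modulator_mirna_ids']}")
print(f"sensitivity        : {report.sensitivity:.2f}   "
      f"(fraction of planted miRNAs flagged)")
print(f"false positive rate: {report.false_positive_rate:.3f} "
      f"(null miRNAs wrongly flagged)")
print(f"sign agreement     : {report.sign_agreement:.2f}   "
      f"(TES sign matches the planted coupling direction)")
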