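"""Risk-score evaluation: cutoff, KM/log-rank, tdAUC, C-index, calibration,
decision curve, and two-marker stratification."""

import numpy as np
import pandas as pd

from pathmir import (
    SurvivalTable,
    assign_groups,
    clinical_utility,
    correlate_markers,
    km_logrank,
    optimal_cutoff,
    performance_metrics,
    stratify_two_markers,
)

rng = np.random.default_rng(1)
n = 200
ids = [f"p{i}" for i in range(n)]
score = pd.Series(rng.normal(size=n), index=ids)
time = rng.exponential(1.0 / (0.06 * np.exp(0.9 * score)))
event = (rng.random(n) > 0.25).astype(int)
surv = SurvivalTable(pd.DataFrame(
    {"time": np.minimum(time, 60), "event": np.where(time > 60, 0, event)},
    index=ids))

cutoff = optimal_cutoff(score, surv)
comp = km_logrank(assign_groups(score, cutoff), surv)
print(f"optimal cutoff = {cutoff:.3f}")
print(f"high vs low HR = {comp.hr:.2f} [{comp.hr_ci[0]:.2f}, {comp.hr_ci[1]:.2f}], "
      f"log-rank p = {comp.logrank_p:.2e}")
print("(the cutoff is chosen to maximize this statistic, so the p-value is "
      "optimistic by construction)\n")

perf = performance_metrics(score, surv, times=[6.0, 12.0, 24.0])
print(f"C-index = {perf.c_index:.3f} "
      f"[{perf.c_index_ci[0]:.3f}, {perf.c_index_ci[1]:.3f}]")
for t, a in perf.auc_at_times.items():
    print(f"  AUC({t:g} months) = {a:.3f}")

cal, nb = clinical_utility(score, surv, time_horizon=12.0)
print("\ncalibration by score tertile at 12 months:")
print(cal.round(3))
print("\nnet benefit at selected thresholds:")
print(nb[nb["threshold"].round(2).isin([0.1, 0.3, 0.5])].round(3), "\n")

marker = pd.Series(0.6 * score + rng.normal(size=n), index=ids)
r, p = correlate_markers(score, marker)
print(f"score vs marker: r = {r:.3f}, p = {p:.2e}")
strat = stratify_two_markers(assign_groups(score, cutoff), marker,
                             float(marker.median()), surv)
print(f"four-group omnibus log-rank p = {strat.omnibus_p:.2e}; group sizes: "
      f"{strat.groups.value_counts().to_dict()}")
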