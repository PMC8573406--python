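"""Count normalization, quantile normalization and cohort harmonization.

Mirrors the usual preprocessing path for a sequencing cohort (counts ->
RPM/TPM, zero-fraction filter) and an array cohort (quantile normalization),
then restricts both to their shared features.
"""

import numpy as np
import pandas as pd

from pathmir import (
    ExpressionMatrix,
    filter_low_expression,
    harmonize_cohorts,
    normalize_counts,
    quantile_normalize,
    zscore_by_feature,
)

counts = ExpressionMatrix(
    pd.DataFrame(
        {"s1": [10, 30, 60, 0], "s2": [5, 0, 90, 0], "s3": [8, 12, 40, 0]},
        index=["mir-a", "mir-b", "mir-c", "mir-d"], dtype=float),
    unit_tag="count")

rpm = normalize_counts(counts, "rpm")
print("RPM (each column rescaled to 1e6 total):")
print(rpm.data.round(0), "\n")

kept = filter_low_expression(rpm, max_zero_fraction=0.5)
print(f"zero-fraction filter: {counts.n_features} -> {kept.n_features} features "
      "(mir-d is zero in every sample)\n")

array = ExpressionMatrix(
    pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
                 index=["mir-a", "mir-b", "mir-x"]),
    unit_tag="array_intensity")
qn = quantile_normalize(array)
print("quantile normalization forces both samples onto the mean distribution:")
print(qn.data, "\n")

seq, arr = harmonize_cohorts([kept, qn])
print(f"shared features after harmonization: {seq.feature_ids}")
print("z-scored sequencing cohort (per feature, mean 0 / sd 1):")
print(zscore_by_feature(seq).data.round(3))
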