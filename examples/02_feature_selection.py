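"""Rank features by two-sample t-test and select below a p-value threshold.

Extracts preferred-phase-angle features from a phase-effect cohort, ranks
every (channel, band) feature by its TD-vs-ASD t-test p-value, and shows
that the selected features concentrate on the truly affected channels and
band.
"""

import numpy as np

from ppafuse import (
    extract_feature_matrix,
    generate_cohort,
    preset_specs,
    select_by_threshold,
    ttest_rank,
)

spec_td, spec_asd = preset_specs("phase-only")  # theta effect on channels 0-4
cohort = generate_cohort(15, spec_td, spec_asd, seed=7)
fm = extract_feature_matrix(cohort.recordings, "PPA")

result = select_by_threshold(ttest_rank(fm), threshold=0.005)
print(f"{result.n_selected} of {fm.n_features} features selected at p < 0.005\n")
print(f"{'rank':>4}  {'channel':<8} {'band':<10} {'p-value':>10}")
for rank, idx in enumerate(result.selected_indices[:10], 1):
    d = fm.descriptors.iloc[idx]
    print(f"{rank:>4}  {d['channel']:<8} {d['band']:<10} {result.p_values[idx]:>10.2e}")

truth = {f"SY{i + 1:03d}" for i in range(5)}
hits = sum(
    fm.descriptors.iloc[i]["channel"] in truth
    and fm.descriptors.iloc[i]["band"] == "theta"
    for i in result.selected_indices
)
print(f"\n{hits} selected features lie in the injected effect")
print("(theta band, channels SY001-SY005) - selection recovers the truth.")
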