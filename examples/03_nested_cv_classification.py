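"""Classify a synthetic cohort with nested fivefold cross-validation.

Runs the full protocol on a cohort that carries both a phase effect
(theta band) and a power effect (alpha band) on disjoint channels:
per fold, z-scoring and t-test selection are fitted on the 36 training
subjects, the p-value threshold is tuned on the 12 validation subjects,
and the 12 held-out test subjects are scored once.  Prints the summary
table for the power model, the phase model, and both fusion modes.
"""

from ppafuse import ExperimentConfig, generate_cohort, preset_specs, run_experiment

spec_td, spec_asd = preset_specs("both")
cohort = generate_cohort(30, spec_td, spec_asd, seed=11)

result = run_experiment(cohort.recordings, ExperimentConfig(seed=11))
report = result.report()
print(report.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

print()
print("accuracy/sensitivity/specificity are mean % over the five test")
print("folds (+/- SEM columns); sensitivity is ASD recall, specificity TD")
print("recall. p_threshold is the validation-tuned selection threshold,")
print("n_selected the mean number of features below it, and fusion_weight")
print("the validation-tuned PSD weight of the score-level combination.")
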