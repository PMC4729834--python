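"""Classify mitotic phases with class-imbalance-aware boosting.

Mitotic cells are ~5% of the population, so each boosting stage
undersamples the majority classes before fitting its weak tree.
"""

from cytocycle import (PopulationConfig, RUSBoostParams, cross_validate,
                       generate_population, merge_phase_labels)
from cytocycle.pipeline import prepare_profiles

records, truth = generate_population(PopulationConfig(n_cells=1000, seed=3))
features, _, _ = prepare_profiles(records, seed=3)
labels = merge_phase_labels(truth.set_index("cell_id").loc[features.index, "phase"])

report = cross_validate(features, labels, k=5, task="classification", seed=3,
                        params=RUSBoostParams(M=40))
print("per-class true-positive rates (mean over folds):")
for phase, tpr in sorted(report.mean.items()):
    print(f"  {phase:11s} {tpr:.2f}")
print(report.confusion)
# each row of the confusion matrix is a true phase; the diagonal over the
# row sum is that phase's recall (TPR).
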