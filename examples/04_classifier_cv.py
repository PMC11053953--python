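"""Leave-subjects-out classification of synthetic emotion cohorts.

Generates a small cohort whose five classes carry disjoint annular pulsatile
amplitude patterns, extracts I_AC feature blocks through the full pipeline,
and trains the small CNN under subject-grouped cross-validation.  A larger
version of this experiment (20 subjects) is what scripts/acceptance.py runs.
"""

import numpy as np

import pulsemap as pm
from pulsemap.experiments import classifier_recovery

report = classifier_recovery(signal=True, n_subjects=8, clips_per_subject=5,
                             seed=3, epochs=120, group_size=4)
print(f"folds: {report.fold_accuracies.round(2)}")
print(f"overall accuracy = {report.accuracy:.2f} (chance = 0.20)")
mean_f1, sd_f1 = report.macro["f1"]
print(f"macro F1 = {mean_f1:.2f} +/- {sd_f1:.2f}")
print("row-normalized summed confusion matrix (rows = true class "
      f"{report.classes}):")
print(np.round(report.row_normalized, 2))
# Accuracy far above 0.20 shows the pipeline preserves class-specific
# spatial amplitude structure and the harness generalizes across subjects.
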