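"""Compare CP and Paralind by missing-data cross-validation.

Each replicate adds 30% relative Gaussian noise to the cohort, hides 20% of
the entries (the same pattern for both models), refits both models on the
masked, re-preprocessed data and scores the reconstruction at the hidden
entries (tensor completion score, lower = better). The paired t-test across
replicates tells whether the restricted model generalizes better.

Ten replicates here to keep the example quick; the study design uses twenty.
"""

import numpy as np

import dynamet as dm
from dynamet.diagnostics import ModelSpec

from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).parent))
from _cohorts import linear_two_group_cohort  # noqa: E402

tensor = linear_two_group_cohort(beta=0.01, seed=1)

report = dm.crossval_compare(
    tensor.values,
    [ModelSpec("cp", 2, n_starts=3, tol=1e-9),
     ModelSpec("paralind", 2, S=1, n_starts=3, tol=1e-9)],
    eta=0.3, missing_fraction=0.2, n_reps=10, seed=1,
)

for label, values in report.tcs_values.items():
    print(f"{label:18s} median TCS = {np.median(values):.4f}")
print(f"paired t-test p-value = {report.paired_p:.4f}")
print("\nA lower TCS for Paralind(1,2,2) with p < 0.05 says the restricted "
      "model recovers held-out entries better — evidence that the rank "
      "deficiency is real structure, not an artifact.")
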