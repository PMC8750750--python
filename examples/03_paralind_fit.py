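"""Fit the Paralind(1,2,2) model and read off the group separation.

When the 2-component CP model is rank deficient in the subjects mode, the
restricted Paralind model makes the shared subject profile explicit: both
components use the single basis column of A (dependency matrix H = [1 1]),
the metabolites factor is orthogonal and the time factor non-negative. The
single subject vector then separates normal from knock-down subjects.
"""

import numpy as np

import dynamet as dm

from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).parent))
from _cohorts import linear_two_group_cohort  # noqa: E402

tensor = linear_two_group_cohort(beta=0.01, seed=1)
X_pp, _ = dm.preprocess(tensor.values)

cp2 = dm.fit_cp(X_pp, dm.FitOptions(n_components=2, n_starts=8, seed=0))
c12 = dm.cosine_similarity(cp2.A[:, 0], cp2.A[:, 1])
print(f"CP(R=2): fit = {cp2.fit:.2f}%  subject-mode C12 = {c12:+.2f}")

H = dm.dependency_matrix(1, 2, [1, 1])
pl = dm.fit_paralind(X_pp, 1, 2, H)
print(f"Paralind(1,2,2): fit = {pl.fit:.2f}%  (slightly below CP: one fewer "
      "free subject profile)")

a = pl.A[:, 0]
print("\nsubject scores (basis column of A):")
print("  normal    mean %+.3f" % a[:10].mean())
print("  knock-down mean %+.3f" % a[10:].mean())
print("groups separated by sign:", set(np.sign(a[:10])) != set(np.sign(a[10:])))
# The jump between metabolites M6 and M7 in the metabolites factor reflects
# the halved A(7,6) rate — the model localizes the induced change.
print("\nmetabolites factor, component 1 (note the jump between M6 and M7):")
print(np.round(pl.B[:, 0], 2))
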