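"""Test a simulated two-group community with all three FDR procedures.

Builds a sparse community of 220 taxa (20 truly differential, 20 null,
180 rare) with 15 samples per group, then runs the discrete permutation
FDR procedure (dsfdr), filtered BH (fbh) and plain BH (bh) at q = 0.1 on
a shared set of 1000 label permutations. Because the ground truth is
known, the printed true/false discovery split shows each procedure's
realized FDR and power on this draw: the discrete procedure typically
recovers the most truly differential taxa while keeping false discoveries
near or below the nominal 10%.
"""

import numpy as np

from dsfdr import SimulationSpec, build_null, simulate_community
from dsfdr.evaluation import apply_method

dataset = simulate_community(
    SimulationSpec(
        n_per_group=15, n_differential=20, n_null=20, n_rare=180, seed=42
    )
)
profile = build_null(dataset.matrix, dataset.groups, "meanrank", B=1000, seed=7)

print(f"{dataset.matrix.n_features} taxa, "
      f"{dataset.matrix.n_samples} samples, q = 0.1\n")
print(f"{'method':>6} {'rejected':>9} {'true':>5} {'false':>6} {'FDP':>6}")
for method in ("dsfdr", "fbh", "bh"):
    rejected = apply_method(method, dataset, profile, q=0.1)
    tp = int((rejected & dataset.truth).sum())
    fp = int((rejected & ~dataset.truth).sum())
    fdp = fp / max(tp + fp, 1)
    print(f"{method:>6} {tp + fp:>9} {tp:>5} {fp:>6} {fdp:>6.3f}")
print("\n'true'/'false' split uses the simulator's ground truth; "
      "FDP is the realized false-discovery proportion.")
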