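"""Build the four similarity views and the integrated matrices.

Generates a small planted dataset (two groups of circRNAs/drugs whose
sequences, fingerprints and associations all share the group structure) and
prints representative entries of each similarity channel.
"""

import numpy as np

from mnclcda import build_similarity_bundle
from mnclcda.synthetic import SyntheticSpec, generate

dataset, truth = generate(SyntheticSpec(Nc=12, Nd=8, groups=2, seed=1))
bundle = build_similarity_bundle(dataset, dataset.Y)

groups = np.array(truth["circ_groups"])
same = (groups[:, None] == groups[None, :]) & ~np.eye(12, dtype=bool)

print(f"sequence similarity  SC: within-group mean {bundle.SC[same].mean():.3f}, "
      f"between-group mean {bundle.SC[~same & ~np.eye(12, dtype=bool)].mean():.3f}")
print(f"interaction kernel   GC: bandwidth r_c = {bundle.r_c:.3f}, "
      f"off-diagonal mean {bundle.GC[~np.eye(12, dtype=bool)].mean():.3f}")
print(f"integrated           CS[0,1] = {bundle.CS[0,1]:.3f} "
      f"(= (SC[0,1] + GC[0,1]) / 2 = ({bundle.SC[0,1]:.3f} + {bundle.GC[0,1]:.3f}) / 2)")

dg = np.array(truth["drug_groups"])
same_d = (dg[:, None] == dg[None, :]) & ~np.eye(8, dtype=bool)
print(f"drug structure       SD: within-group mean {bundle.SD[same_d].mean():.3f}, "
      f"between-group mean {bundle.SD[~same_d & ~np.eye(8, dtype=bool)].mean():.3f}")
print("\nPlanted same-group pairs are more similar in every channel; the")
print("integrated matrices average the biological and interaction-profile views.")
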