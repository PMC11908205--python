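"""Build a tiny three-sample genealogy by hand and print every
relatedness matrix the package defines for it.

The tree: samples a, b, c at time 0; a and b coalesce at time 1 (node m);
their ancestor joins c at the root (time 2).  Spans are 1, so branch
"areas" equal branch lengths.
"""

import numpy as np

from branchgrm import (
    TreeSequence,
    branch_grm_centered,
    branch_grm_uncentered,
    divergence_matrix,
    egrm,
)

ts = TreeSequence(
    sequence_length=1.0,
    node_time=[0, 0, 0, 1, 2],
    node_is_sample=[1, 1, 1, 0, 0],
    edge_left=[0] * 4,
    edge_right=[1] * 4,
    edge_parent=[3, 3, 4, 4],
    edge_child=[0, 1, 3, 2],
)

np.set_printoptions(precision=3, suppress=True)
C = branch_grm_uncentered(ts).values
print("uncentered branch GRM C (shared ancestral branch area):\n", C)
print("C[a,b] = 1: a and b share only the branch above their ancestor m.")
print("C[a,a] = 2: a's own leaf branch (1) plus the shared branch (1).\n")

B = branch_grm_centered(ts).values
print("centered branch GRM B = PCP (trait covariance after centering):\n", B)
print("rows sum to zero; B is what PCA and mixed models consume.\n")

D = divergence_matrix(ts).values
print("branch divergence D (span-weighted path length between samples):\n", D)
print("check: B equals -PDP/2 ->",
      np.allclose(B, -(D - D.mean(0) - D.mean(1)[:, None] + D.mean()) / 2))

E = egrm(ts).values
print("\neGRM (per-edge variance-normalized, divided by total area):\n", E)
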