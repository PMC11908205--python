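"""Randomized PCA of the centered branch GRM, checked against the dense
eigendecomposition.  The randomized route only ever touches the GRM
through matrix-free products, so it extends to cohorts where the dense
matrix would not fit in memory.
"""

import numpy as np

from branchgrm import SimulationConfig, exact_pca, randomized_pca, simulate_coalescent_ts

cfg = SimulationConfig(
    n_samples=150, effective_size=1.0, recombination_rate=2.0, seed=5,
)
ts = simulate_coalescent_ts(cfg)
print(f"simulated {ts.num_samples} samples, {ts.num_trees} local trees")

res = randomized_pca(ts, k=4, q=5, seed=42)
ref = exact_pca(ts, k=4)

np.set_printoptions(precision=4, suppress=True)
print("randomized eigenvalues:", res.eigenvalues)
print("exact eigenvalues:     ", ref.eigenvalues)
print("max relative error:    ",
      float(np.abs(res.eigenvalues / ref.eigenvalues - 1).max()))
print("the eigenvalues are the variances of the trait model captured by")
print("each principal axis; the components (res.components) are the PCs.")
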