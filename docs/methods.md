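# Methods

This note documents the models implemented in `branchgrm`, the parameter
conventions, the numerical choices, and what the synthetic-data generators
do and do not emulate.

## Data model

A tree sequence is a node table (per-genome birth time in generations, a
sample flag, an optional diploid-individual index) and an edge table
(`[left, right)` genome interval, parent, child).  Coordinates are 0-based
half-open; within every breakpoint interval the edges must form a forest,
which is guaranteed by two validated invariants: `time(parent) >
time(child)` on every edge and per-child disjoint intervals.  Local trees
are recovered by a sweep with insertions ordered by `(left, parent time
ascending)` and removals by `(right, parent time descending)`, so children
are always attached below already-valid parents and removals at a
breakpoint precede insertions.  Multiple roots per local tree are allowed;
pairs of samples in different root-subtrees have zero shared area, and
their divergence is treated as an error rather than infinity.

MRCA queries use per-tree ancestor-chain intersection, O(height) per
query.  Constant-time preprocessing schemes exist, but every consumer in
this package is either desk-scale or avoids MRCA queries entirely, so the
simple method is the right trade-off; the interface would admit a faster
backend unchanged.

## Relatedness matrices

With `A(i,j)` the total span-weighted length of branches ancestral to both
samples, and `U, V` uniform with replacement over the sample set:

* divergence `D_ij = Σ_k s_k (2 t_mrca(i,j,k) − t_i − t_j)`;
* uncentered branch GRM `C_ij = A(i,j)`;
* centered branch GRM `B = PCP = −PDP/2`, `P = I − 11ᵀ/n`;
* eGRM: each edge's centered-indicator outer product weighted by
  `s_k b_e / (S̄(1−S̄))`, summed and divided by the total area `A_T`;
* genotype GRM `(1/n_L) Σ_ℓ (G_iℓ − p̄_ℓ)(G_jℓ − p̄_ℓ)` on dosages in
  `[0,1]`, and the allele-match covariance
  `½[P(X_i=X_j) − P(X_i=X_U) − P(X_j=X_V) + P(X_U=X_V)]`, which is
  algebraically identical on binary input.

Centering always samples `U, V` uniformly *with replacement* — this is
what puts `A(U,U)`-type terms into the diagonal and makes `B` exactly the
doubly centered `C`.  No frequency weighting is applied beyond the eGRM's
`S̄(1−S̄)` denominator (the α = 0 convention); edges with `S̄ ∈ {0, 1}`
carry no variance and are skipped.  Dosages are *proportions* of
non-ancestral alleles, so the diploid genotype GRM is 1/4 of the
count-based convention; `collapse_to_individuals` averages a per-copy
matrix over the copy pairs of each individual, which matches that
convention exactly.

Branch matrices are materialized per tree from a compact indicator matrix
`S` (sample-ancestral nodes × samples, built by climbing each sample's
root path), as `Σ_k s_k Sᵀ diag(ℓ) S`.  Pairwise TMRCAs come from an
independent route — scanning the same nodes in increasing time order and
recording the first node covering each pair — so identity tests compare
genuinely different computations.

## The incremental matrix-free product

The product `y = Cw` is computed in one sweep of the edge events.  Per
node the state is `w(n)` (current subtree weight), `v(n)` (value
accumulated at n, destined for everything below), and `x(n)` (position of
the last update); the pending contribution of the branch above `n` is
`z(n) = ℓ(n)(b_k − x(n))`.  Removing edge `(c, p)` first flushes
`v(c) += z(c)w(c)` — the pending area of the removed branch itself — then
walks from `p` to the root, flushing each ancestor, subtracting `w(c)`,
and cascading every ancestor's `v` into `v(c)`.  Insertion mirrors this
with opposite signs, so a subtree re-attached at `b_k` later receives only
value accrued while attached.  After the removals at the right end of the
genome, `y_s = v(s)`.

Two details deserve emphasis because the prose descriptions of such sweeps
are ambiguous.  First, the flush of the removed edge's own pending area is
required: without it the leaf branches of a one-tree sequence contribute
nothing and the product is simply wrong (the two-sample identity matrix
becomes zero).  Second, the cascade `v(c) += v(n)` applies at *every* node
on the walk, because each node holds only its own deltas; correctness of
both choices is established empirically by exact agreement (to float
roundoff) with the materialized matrix on batches of simulated sequences,
and independently against the reference tree-sequence library.

Samples must be leaves; a sample appearing as an edge parent is rejected
loudly rather than silently mis-weighted.  The sweep allocates O(#nodes)
scalars and never forms an n × n array (asserted by a peak-memory test).
Centered products apply `P` as mean subtraction around a single uncentered
product; quadratic forms `uᵀCw` use one product and a dot product.

Instrumentation counts nodes touched per breakpoint.  The initial tree
build (all edges inserted at position 0) and the terminal flush (all edges
removed at the genome end) are the O(n) phases; the per-transition counter
excludes them, leaving the quantity that the O(t log n) term describes.

## Randomized PCA

`B` is symmetric PSD, so principal components are eigenvectors.  Range
estimation draws a Gaussian test block, orthonormalizes `B·Ω` by economy
QR, and refines with `q` power iterations (default q = 5); the small
factor `W = QᵀB` is decomposed by exact SVD, and its singular values are
the eigenvalues of `B` restricted to the captured subspace.  By default
`k + 10` oversampled columns are drawn and truncated to `k` (capped at the
matrix dimension); a `paper_mode` flag uses exactly `k` columns for
fidelity with the minimal scheme.  One named seed drives the single
Gaussian draw, so results are bit-reproducible.  Individual-level PCA
applies the copy-averaging operator around the product; both centering
orders (over genome copies before collapsing, or over individuals after)
are exposed, since the choice is a genuine convention.

## Synthetic data

*Coalescent generator.*  The leftmost tree is a Kingman coalescent with
pair rate `1/N_e` (haploid `N_e`; expected pairwise TMRCA `N_e`).  Moving
right, breakpoints arrive at genomic rate ρ × total branch length; at each
one a uniformly chosen point on the branches is cut, the lineage above it
is erased up to its coalescent node, and the floating subtree re-coalesces
with the remaining tree at rate (lineages alive)/`N_e`.  This is the
classic SMC approximation: marginal trees are coalescent-distributed,
correlations between distant trees are simplified.  That suffices here
because every downstream check is either an exact identity on whatever
sequence is produced or a marginal-expectation comparison.

*Mutations and traits.*  Mutations are Poisson with rate μ per unit branch
area, placed uniformly on the tree interval, each founding a binary site;
genotypes are descent indicators.  Trait effects are i.i.d. Normal(0, σ²)
per site.  The Monte-Carlo checker verifies Cov = σ²·n_L·C (site mode,
fixed mutations) and Cov = σ²·μ·B (branch mode, re-dropped mutations)
against elementwise Monte-Carlo standard errors.

*Pedigrees.*  Kinship uses the standard tabular recursion with unknown
parents treated as unique founders.  `make_pedigree` builds random-mating
monogamous generations with configurable sibships;
`relationship_panel_pedigree` deterministically constructs labelled
sibling and first/second/third-cousin proband pairs, all in the same final
generation, each k-th-cousin pair descending from one ancestral couple
k + 1 generations up through lines that marry fresh founders.

*Gene-drop and recapitation.*  Each individual contributes two genome-copy
nodes; a non-founder copy is a Mendelian mosaic of its parent's two copies
with Poisson(ρL) crossovers per meiosis.  Node times are generations
before the probands.  Recapitation completes each local tree's open
founder lineages with an independent Kingman coalescent (staggered lineage
activation at founder times).  Coalescing trees independently is a
deliberate simplification: it preserves each tree's marginal distribution
— all the pedigree comparisons use — but discards linkage between founder
lineages across neighbouring trees, so cross-tree covariances of deep
coalescence times are not faithful.  A genuinely linked recapitation would
be required for, e.g., variance decompositions of genome-wide statistics
across the founder boundary.

## Study conditions and problem sizes

The exact-identity and product-oracle checks run on batches of 100
simulated sequences with 4–64 samples and up to 200 local trees, in
coalescent units (`N_e = 1`, unit genome): identities are scale-free, so
small units keep the checks fast without weakening them.  The
mutation-duality check uses 32 samples, `N_e = 100`, and a recombination
rate giving ≈ 40 trees, so that at μ = 1 each replicate carries several
hundred segregating sites: with 200 replicates the Poisson averaging error
of the mean genotype GRM sits well inside the 5 % relative-Frobenius
budget the check asserts (a standard power consideration, fixed before
running the batteries).  The pedigree study uses the labelled panel with
four pairs per relationship type plus unrelated fillers, a 1-unit genome
with ρ = 3 crossovers per meiosis (a long-chromosome genetic length), and
recapitation at `N_e = 100`, which puts the mean TMRCA (≈ 100 generations)
well above the pedigree depth (4) — the regime in which B ≈ r·T holds.
Across 100 replicates the regression of mean collapsed branch relatedness
on kinship recovers T within a few percent, and the replicate SD of branch
relatedness decreases monotonically from siblings to third cousins.  (The
*relative* spread runs the other way — realized relatedness of distant
relatives is proportionally noisier — so the ordering claim is about
absolute SD, which is what the replicate boxplot spread shows.)  The
scaling study instruments n = 2⁷…2¹² with ≈ 60–80 trees each; the mean
interior-transition cost grows consistently with log₂ n and far below
linear.

## Numerical choices and edge cases

* Exact identities are asserted at 1e−9 relative tolerance; measured
  residuals are at machine precision (~1e−15).
* Tied event positions follow the edge-order contracts above; tied times
  have probability zero under the continuous generators.
* Degenerate inputs error loudly: empty sample sets, non-leaf samples in
  the product path, pairs without a common root in divergence, zero total
  area in the eGRM, `k` exceeding the matrix dimension in PCA.  A zero
  GRM yields zero eigenvalues with a warning.
* Genetic-map remapping is piecewise-linear interpolation of edge and
  site coordinates; node times are untouched.  Mean TMRCA is invariant
  under uniform rescaling but not under non-uniform maps, which reweight
  local trees.
* Table I/O writes full precision (`%.17g`) and reads with round-trip
  float parsing, so save/load is byte-stable.

## Known limitations

* The SMC generator and per-tree recapitation are approximations by
  design (see above); neither is suitable as a ground-truth simulator of
  linkage structure.
* Samples must be leaves for the matrix-free product; internal samples
  would need the generalized weighting scheme, which is out of scope.
* Sites are biallelic with a single mutation each (infinite-sites
  placement); recurrent and multi-allelic mutation are not modelled.
* Pedigree founders are treated as completely unrelated; founder
  inbreeding would need explicit founder kinship input.
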