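"""Materialized relatedness matrices and the identities connecting them.

All "branch" matrices are span-weighted sums over local trees, in units of
generations x genome length.  With A(i, j) the total area of branches
ancestral to both samples i and j, and U, V uniform (with replacement)
random samples:

* divergence      D_ij = sum_k s_k (2 t_mrca(i,j,k) - t_i - t_j)
* uncentered GRM  C_ij = A(i, j)
* centered GRM    B_ij = E[A(i,j) - A(i,U) - A(j,V) + A(U,V)] = P C P
                       = -P D P / 2        with P = I - 11'/n
* eGRM            per-edge normalization of B by Sbar(1 - Sbar), divided
                  by the total ARG area.

The genotype-side analogues (genotype GRM and allele-match covariance) are
dimensionless and agree with each other exactly on binary matrices; the
branch matrices are their expectations under a Poisson mutation process on
edge area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import Pedigree, kinship_matrix
from .trees import LocalTree, TreeSequence, iterate_trees

__all__ = [
    "RelatednessMatrix",
    "divergence_matrix",
    "branch_grm_uncentered",
    "branch_grm_centered",
    "egrm",
    "genotype_grm",
    "match_covariance",
    "collapse_to_individuals",
    "pedigree_kinship",
    "trait_covariance_check",
    "centering_matrix",
    "tmrca_matrices",
]


@dataclass(frozen=True)
class RelatednessMatrix:
    """A dense symmetric relatedness matrix tagged with its mode.

    ``mode`` is one of ``divergence_D``, ``uncentered_C``, ``centered_B``,
    ``egrm``, ``genotype``, ``match_cov``, ``pedigree_kinship``; ``unit``
    is "generations*span" for branch modes and "dimensionless" otherwise.
    """

    values: np.ndarray
    mode: str
    unit: str = "generations*span"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relatedness matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def centering_matrix(n: int) -> np.ndarray:
    """P = I - 11'/n (projects out the constant vector)."""
    return np.eye(n) - np.full((n, n), 1.0 / n)


def _center(M: np.ndarray) -> np.ndarray:
    row = M.mean(axis=1, keepdims=True)
    col = M.mean(axis=0, keepdims=True)
    return M - row - col + M.mean()


# ---------------------------------------------------------------------------
# branch-mode matrices
# ---------------------------------------------------------------------------

def _shared_area_and_roots(ts: TreeSequence):
    """Per-genome sums used by the branch matrices.

    Returns ``(C, R, coverage)``: the shared-area matrix C_ij = A(i, j),
    the root-path lengths R_i = sum_k s_k d(i, root_k), and a boolean
    matrix marking pairs that share a root in every local tree.
    """
    n = ts.num_samples
    C = np.zeros((n, n))
    R = np.zeros(n)
    same_root = np.ones((n, n), dtype=bool)
    for tree in ts.trees():
        nodes, S = tree.sample_paths()
        ell = np.array([tree.branch_length(n_) for n_ in nodes])
        w = tree.span * ell
        C += S.T @ (w[:, None] * S)
        R += w @ S
        # root membership: nodes with no parent partition the samples
        root_rows = [a for a, n_ in enumerate(nodes) if tree.parent[n_] == -1]
        member = np.zeros(n)
        for a in root_rows:
            member = member + (a + 1) * S[a]
        same_root &= member[:, None] == member[None, :]
    return C, R, same_root


def branch_grm_uncentered(ts: TreeSequence) -> RelatednessMatrix:
    """Uncentered branch GRM: C_ij = total area of branches ancestral to
    both i and j (samples in different root-subtrees share area 0)."""
    if ts.num_samples == 0:
        raise ValueError("tree sequence has no samples")
    C, _, _ = _shared_area_and_roots(ts)
    return RelatednessMatrix(C, mode="uncentered_C")


def divergence_matrix(ts: TreeSequence) -> RelatednessMatrix:
    """Branch divergence D_ij: span-weighted path length between samples.

    Raises when a pair of samples lacks a common root in some local tree
    (their divergence is undefined there).
    """
    n = ts.num_samples
    D = np.zeros((n, n))
    t0 = ts.node_time[ts.samples]
    for tree in ts.trees():
        Tm, covered = _tmrca_one_tree(tree)
        if not covered.all():
            i, j = np.argwhere(~covered)[0]
            raise ValueError(
                f"samples {int(tree.samples[i])} and {int(tree.samples[j])} have no "
                f"common root in the tree on [{tree.left}, {tree.right})"
            )
        D += tree.span * (2.0 * Tm - t0[:, None] - t0[None, :])
    np.fill_diagonal(D, 0.0)
    return RelatednessMatrix(D, mode="divergence_D")


def _tmrca_one_tree(tree: LocalTree):
    """Pairwise TMRCA matrix for one local tree.

    Processes sample-ancestral nodes in increasing time order; the first
    node covering a pair is its MRCA.  Returns ``(Tm, covered)`` where
    uncovered pairs lie in different root-subtrees.
    """
    nodes, S = tree.sample_paths()
    n = S.shape[1]
    times = tree.node_time[nodes]
    order = np.argsort(times, kind="stable")
    Tm = np.zeros((n, n))
    covered = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(Tm, tree.node_time[tree.samples])
    np.fill_diagonal(covered, True)
    for a in order:
        row = S[a] > 0
        if row.sum() < 2:
            continue
        pair = np.outer(row, row) & ~covered
        if pair.any():
            Tm[pair] = times[a]
            covered |= pair
        if covered.all():
            break
    return Tm, covered


def tmrca_matrices(ts: TreeSequence):
    """Yield ``(tree, Tm)`` per local tree; errors if a pair never shares
    a root.  Exposed for the TMRCA-form identities."""
    for tree in ts.trees():
        Tm, covered = _tmrca_one_tree(tree)
        if not covered.all():
            raise ValueError(
                f"pair without a common root in the tree on [{tree.left}, {tree.right})"
            )
        yield tree, Tm


def branch_grm_centered(ts: TreeSequence) -> RelatednessMatrix:
    """Centered branch GRM B = P C P (equivalently -P D P / 2)."""
    C = branch_grm_uncentered(ts).values
    return RelatednessMatrix(_center(C), mode="centered_B")


def egrm(ts: TreeSequence) -> RelatednessMatrix:
    """Expected-GRM normalization of branch relatedness.

    Each edge's centered-indicator outer product is divided by
    Sbar(1 - Sbar) (the variance of the edge's descendant indicator) and
    the sum is divided by the total ARG area A_T.  Edges with Sbar in
    {0, 1} carry no variance and are skipped.
    """
    n = ts.num_samples
    G = np.zeros((n, n))
    area = 0.0
    for tree in ts.trees():
        nodes, S = tree.sample_paths()
        ell = np.array([tree.branch_length(n_) for n_ in nodes])
        area += tree.span * ell.sum()
        sbar = S.mean(axis=1)
        keep = (sbar > 0) & (sbar < 1) & (ell > 0)
        if not keep.any():
            continue
        Sc = S[keep] - sbar[keep, None]
        w = tree.span * ell[keep] / (sbar[keep] * (1.0 - sbar[keep]))
        G += Sc.T @ (w[:, None] * Sc)
    if area == 0:
        raise ValueError("total ARG area is zero; eGRM undefined")
    return RelatednessMatrix(G / area, mode="egrm")


# ---------------------------------------------------------------------------
# genotype-mode matrices
# ---------------------------------------------------------------------------

def genotype_grm(G: np.ndarray) -> RelatednessMatrix:
    """Genotype GRM: C_ij = (1/n_L) sum_l (G_il - pbar_l)(G_jl - pbar_l).

    ``G`` holds per-sample dosages in [0, 1] (haploid genotypes are 0/1;
    diploid dosage is the *proportion* of non-ancestral alleles, which for
    diploids makes this matrix 1/4 of the count-based convention).
    Columns fixed across samples contribute nothing.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise ValueError("genotype matrix must be 2-D with at least one locus")
    if G.min() < 0 or G.max() > 1:
        raise ValueError("genotype entries must lie in [0, 1]")
    Gc = G - G.mean(axis=0, keepdims=True)
    C = (Gc @ Gc.T) / G.shape[1]
    return RelatednessMatrix(C, mode="genotype", unit="dimensionless")


def match_covariance(G: np.ndarray) -> RelatednessMatrix:
    """Allele-match form of the genotype GRM (binary input only).

    C_ij = 1/2 [P(X_i=X_j) - P(X_i=X_U) - P(X_j=X_V) + P(X_U=X_V)]
    with the probabilities over a uniform locus and uniform-with-replacement
    individuals U, V.  Identical to :func:`genotype_grm` on binary input.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise ValueError("genotype matrix must be 2-D with at least one locus")
    if not np.isin(G, (0.0, 1.0)).all():
        raise ValueError("match covariance requires binary genotypes")
    # M_ij = P(X_i = X_j) over a uniform locus
    M = (G @ G.T + (1 - G) @ (1 - G).T) / G.shape[1]
    return RelatednessMatrix(0.5 * _center(M), mode="match_cov", unit="dimensionless")


# ---------------------------------------------------------------------------
# aggregation & pedigree
# ---------------------------------------------------------------------------

def collapse_to_individuals(
    M: RelatednessMatrix, groups: np.ndarray
) -> RelatednessMatrix:
    """Average a per-sample matrix over genome copies of each individual.

    ``groups[s]`` is the individual index of sample ``s``; entry (a, b) of
    the result is the mean of M over sample pairs (s in a, t in b).  For
    two diploids this equals the 2x2 block sum divided by four.
    """
    groups = np.asarray(groups, dtype=np.int64)
    if len(groups) != M.n:
        raise ValueError("groups must assign every sample to an individual")
    ids = np.unique(groups)
    A = np.zeros((M.n, len(ids)))
    for a, g in enumerate(ids):
        members = groups == g
        if not members.any():
            raise ValueError(f"group {g} is empty")
        A[members, a] = 1.0 / members.sum()
    return RelatednessMatrix(A.T @ M.values @ A, mode=M.mode, unit=M.unit)


def pedigree_kinship(ped: Pedigree) -> RelatednessMatrix:
    """Kinship matrix theta over all pedigree individuals (dimensionless;
    the probability a random genome copy of each is IBD in the pedigree)."""
    return RelatednessMatrix(
        kinship_matrix(ped), mode="pedigree_kinship", unit="dimensionless"
    )


# ---------------------------------------------------------------------------
# Monte-Carlo check of the trait model
# ---------------------------------------------------------------------------

def trait_covariance_check(
    ts: TreeSequence,
    sigma2: float,
    n_reps: int,
    seed: int | np.random.Generator,
    mode: str = "site",
    mu: float = 1.0,
):
    """Empirical covariance of centered additive traits.

    In ``site`` mode the tree sequence's mutations are held fixed and only
    the per-site effects (i.i.d. Normal(0, sigma2)) are redrawn; the
    empirical covariance estimates sigma2 * n_L * C_genotype.  In
    ``branch`` mode mutations are additionally re-dropped as a Poisson
    process with rate ``mu`` per unit area each replicate; the covariance
    estimates sigma2 * mu * B.

    Returns ``(cov, se)``: the empirical covariance of the centered trait
    and its elementwise Monte-Carlo standard error.
    """
    from .simulate import drop_mutations, genotypes_from_mutations

    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = ts.num_samples
    prods = np.zeros((n, n))
    prods2 = np.zeros((n, n))
    if mode == "site":
        if ts.site_position is None:
            raise ValueError("site mode requires mutations on the tree sequence")
        G = genotypes_from_mutations(ts)
        for _ in range(n_reps):
            eff = rng.normal(0.0, np.sqrt(sigma2), size=G.shape[1])
            Z = G @ eff
            Zc = Z - Z.mean()
            P = np.outer(Zc, Zc)
            prods += P
            prods2 += P * P
    elif mode == "branch":
        for _ in range(n_reps):
            tsm = drop_mutations(ts, mu, rng)
            G = genotypes_from_mutations(tsm)
            if G.shape[1]:
                eff = rng.normal(0.0, np.sqrt(sigma2), size=G.shape[1])
                Z = G @ eff
                Zc = Z - Z.mean()
            else:
                Zc = np.zeros(n)
            P = np.outer(Zc, Zc)
            prods += P
            prods2 += P * P
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cov = prods / n_reps
    var = prods2 / n_reps - cov**2
    se = np.sqrt(np.maximum(var, 0.0) / n_reps)
    return cov, se
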