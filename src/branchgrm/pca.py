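"""Randomized PCA of the centered branch GRM, matrix-free.

The centered branch GRM B is symmetric positive semi-definite, so its
principal components are its leading eigenvectors.  The randomized scheme
needs only products B @ vector, supplied by the incremental sweep of
:mod:`branchgrm.matvec`; B itself is never materialized:

1. Range estimation - draw a Gaussian test matrix Omega, form an
   orthonormal basis Q of B @ Omega by economy QR, and refine it with q
   power iterations (Q <- qr(B @ Q)).
2. Small factorization - W = Q' B (one product per basis column); an exact
   SVD of the small factor W gives singular values (= eigenvalues of B on
   the captured subspace, since B is PSD) and components Q @ U.

By default ``k + 10`` oversampled basis columns are used and the result is
truncated to k (standard practice for accuracy); ``paper_mode=True``
switches to exactly k Gaussian columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matvec import centered_grm_vector_product
from .relatedness import branch_grm_centered
from .trees import TreeSequence

__all__ = ["PCAResult", "randomized_pca", "exact_pca", "pca_individuals"]

DEFAULT_OVERSAMPLE = 10


@dataclass(frozen=True)
class PCAResult:
    """Principal components of the branch GRM.

    ``components`` has orthonormal columns; ``eigenvalues`` are the
    corresponding eigenvalues of B, non-increasing.  ``k``, ``q`` and
    ``seed`` record the randomization (q < 0 and seed < 0 mark an exact
    decomposition).
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    k: int
    q: int
    seed: int


def _randomized_eigh(matvec, n: int, k: int, q: int, seed: int, oversample: int):
    """Core randomized decomposition of an implicit symmetric PSD matrix."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds the matrix dimension {n}")
    p = min(k + oversample, n)
    rng = np.random.default_rng(seed)
    omega = rng.standard_normal((n, p))

    def block(M):
        return np.column_stack([matvec(M[:, j]) for j in range(M.shape[1])])

    Y = block(omega)
    if not np.any(Y):
        # degenerate (zero) matrix: report zero eigenvalues
        import warnings

        warnings.warn("matrix is numerically zero; eigenvalues are all 0")
        return np.eye(n, k), np.zeros(k)
    Q, _ = np.linalg.qr(Y)
    for _ in range(q):
        Q, _ = np.linalg.qr(block(Q))
    W = block(Q).T  # = Q' B  (B symmetric)
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    comps = (Q @ U)[:, :k]
    return comps, s[:k]


def randomized_pca(
    ts: TreeSequence,
    k: int,
    q: int = 5,
    seed: int = 0,
    paper_mode: bool = False,
) -> PCAResult:
    """Randomized PCA of the centered branch GRM of ``ts``.

    All products with B go through the matrix-free sweep; memory stays
    O(n x (k + oversampling)).  Fixing ``seed`` makes the result
    bit-reproducible.
    """
    n = ts.num_samples
    comps, vals = _randomized_eigh(
        lambda v: centered_grm_vector_product(ts, v),
        n,
        k,
        q,
        seed,
        0 if paper_mode else DEFAULT_OVERSAMPLE,
    )
    return PCAResult(components=comps, eigenvalues=vals, k=k, q=q, seed=seed)


def exact_pca(ts: TreeSequence, k: int, max_n: int = 5000) -> PCAResult:
    """Top-k eigenpairs of the materialized centered branch GRM (dense
    reference; guarded against accidental use at large n)."""
    n = ts.num_samples
    if n > max_n:
        raise ValueError(
            f"{n} samples would materialize an n x n matrix; use randomized_pca"
        )
    B = branch_grm_centered(ts).values
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    return PCAResult(
        components=vecs[:, order], eigenvalues=vals[order], k=k, q=-1, seed=-1
    )


def pca_individuals(
    ts: TreeSequence,
    groups: np.ndarray,
    k: int,
    q: int = 5,
    seed: int = 0,
    center: str = "before_collapse",
    paper_mode: bool = False,
) -> PCAResult:
    """PCA of the individual-collapsed branch GRM, still matrix-free.

    ``groups[s]`` maps sample s to its individual.  The collapse is the
    averaging operator A (A'[C]A has entry (a,b) = mean over the copy
    pairs), applied around the sweep.  ``center`` chooses whether the GRM
    is centered over genome copies before collapsing (``before_collapse``,
    the default: PCA of A' B A) or over individuals after collapsing
    (``after_collapse``: PCA of P A' C A P).
    """
    from .matvec import branch_grm_vector_product

    groups = np.asarray(groups, dtype=np.int64)
    n = ts.num_samples
    if len(groups) != n:
        raise ValueError("groups must assign every sample to an individual")
    ids, inv = np.unique(groups, return_inverse=True)
    sizes = np.bincount(inv).astype(float)
    m = len(ids)

    def expand(v):  # A v : individuals -> samples
        return v[inv] / sizes[inv]

    def reduce_(y):  # A' y : samples -> individuals
        return np.bincount(inv, weights=y, minlength=m) / sizes

    if center == "before_collapse":
        def mv(v):
            return reduce_(centered_grm_vector_product(ts, expand(v)))
    elif center == "after_collapse":
        def mv(v):
            vc = v - v.mean()
            y = reduce_(branch_grm_vector_product(ts, expand(vc)))
            return y - y.mean()
    else:
        raise ValueError("center must be 'before_collapse' or 'after_collapse'")
    comps, vals = _randomized_eigh(
        mv, m, k, q, seed, 0 if paper_mode else DEFAULT_OVERSAMPLE
    )
    return PCAResult(components=comps, eigenvalues=vals, k=k, q=q, seed=seed)
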