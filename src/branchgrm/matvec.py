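"""Exact branch-GRM-vector products without materializing the matrix.

The product y = C w with the uncentered branch GRM (C_st = shared ancestral
branch area of samples s and t) is computed in a single left-to-right sweep
of the edge insertion/removal events.  Per node the sweep keeps three lazy
accumulators:

* ``w(n)`` - the sum of input weights over samples below n in the current
  tree,
* ``v(n)`` - the accumulated haplotype value carried by n (contributions of
  branches at-or-above n not yet passed further down), and
* ``x(n)`` - the genome position at which n was last updated, so that the
  pending, not-yet-flushed contribution of the branch above n is
  ``z(n) = branch_length(n) * (current_position - x(n)) * w(n)``.

When an edge (c, p) is removed, the pending contribution of the branch
above c is flushed into v(c); then the walk from p to its root flushes each
ancestor, subtracts w(c) from its subtree weight, and cascades every
ancestor's accumulated value down into v(c).  Insertion mirrors this with
the signs of the w- and v-updates reversed, so that c's subtree later
receives only value accrued while it was attached.  After the removals at
the right end of the genome, y_s = v(s).

Cost per tree transition is proportional to the depth of the affected
nodes; memory is O(#nodes) scalars.  Samples must be leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import NULL, TreeSequence

__all__ = [
    "branch_grm_vector_product",
    "centered_grm_vector_product",
    "quadratic_form",
    "instrument_matvec",
    "MatvecCounters",
]


@dataclass
class MatvecCounters:
    """Operation counts from one instrumented sweep."""

    #: genome position of each breakpoint with edge activity
    positions: list = field(default_factory=list)
    #: nodes touched (flush/walk steps) at each such breakpoint
    nodes_touched: list = field(default_factory=list)

    @property
    def per_transition(self) -> np.ndarray:
        """Nodes touched per interior tree *transition*.

        The initial tree build (all edges inserted at position 0) and the
        terminal flush (all remaining edges removed at the right end of
        the genome) are the O(n) phases of the sweep and are excluded;
        what remains is the per-breakpoint work the O(t log n) term
        describes."""
        return np.asarray(self.nodes_touched[1:-1], dtype=float)


def _check_leaf_samples(ts: TreeSequence) -> None:
    if np.isin(ts.edge_parent, ts.samples).any():
        raise ValueError(
            "matrix-free product requires all samples to be leaves; "
            "a sample node appears as an edge parent"
        )


def branch_grm_vector_product(
    ts: TreeSequence, w: np.ndarray, counters: MatvecCounters | None = None
) -> np.ndarray:
    """Return y with y_s = sum_t C_st w_t for the uncentered branch GRM."""
    w = np.asarray(w, dtype=float)
    samples = ts.samples
    if w.shape != (len(samples),):
        raise ValueError(f"weight vector must have length {len(samples)}")
    _check_leaf_samples(ts)

    nn = ts.num_nodes
    time = ts.node_time
    parent = np.full(nn, NULL, dtype=np.int64)
    W = np.zeros(nn)
    V = np.zeros(nn)
    X = np.zeros(nn)
    W[samples] = w

    I = ts.insertion_order()
    O = ts.removal_order()
    E = ts.num_edges
    eleft, eright = ts.edge_left, ts.edge_right
    epar, echild = ts.edge_parent, ts.edge_child

    j = k = 0
    while j < E or k < E:
        pos = np.inf
        if k < E:
            pos = eright[O[k]]
        if j < E:
            pos = min(pos, eleft[I[j]])
        touched = 0
        # V1: removals (right == pos), upper edges first
        while k < E and eright[O[k]] == pos:
            e = O[k]
            k += 1
            c, p = int(echild[e]), int(epar[e])
            # flush the pending area of the branch above c itself
            V[c] += (time[p] - time[c]) * (pos - X[c]) * W[c]
            X[c] = pos
            touched += 1
            n = p
            while n != NULL:
                pn = parent[n]
                if pn != NULL:
                    V[n] += (time[pn] - time[n]) * (pos - X[n]) * W[n]
                W[n] -= W[c]
                V[c] += V[n]
                X[n] = pos
                touched += 1
                n = pn
            parent[c] = NULL
        # V2: insertions (left == pos), lower parents first
        while j < E and eleft[I[j]] == pos:
            e = I[j]
            j += 1
            c, p = int(echild[e]), int(epar[e])
            X[c] = pos
            touched += 1
            n = p
            while n != NULL:
                pn = parent[n]
                if pn != NULL:
                    V[n] += (time[pn] - time[n]) * (pos - X[n]) * W[n]
                W[n] += W[c]
                V[c] -= V[n]
                X[n] = pos
                touched += 1
                n = pn
            parent[c] = p
        if counters is not None:
            counters.positions.append(float(pos))
            counters.nodes_touched.append(touched)
    return V[samples].copy()


def centered_grm_vector_product(ts: TreeSequence, w: np.ndarray) -> np.ndarray:
    """Return B w = P C (P w) with P the centering projector (applied as
    subtraction of the mean), using a single uncentered product."""
    w = np.asarray(w, dtype=float)
    y = branch_grm_vector_product(ts, w - w.mean())
    return y - y.mean()


def quadratic_form(
    ts: TreeSequence, u: np.ndarray, w: np.ndarray, centered: bool = False
) -> float:
    """u' C w (or u' B w) via one matrix-free product and a dot product."""
    u = np.asarray(u, dtype=float)
    if centered:
        return float(u @ centered_grm_vector_product(ts, w))
    return float(u @ branch_grm_vector_product(ts, w))


def instrument_matvec(
    ts: TreeSequence, w: np.ndarray
) -> tuple[np.ndarray, MatvecCounters]:
    """Run the product while recording root-ward walk lengths per
    breakpoint.  The returned y is identical to the uninstrumented call."""
    counters = MatvecCounters()
    y = branch_grm_vector_product(ts, w, counters=counters)
    return y, counters
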