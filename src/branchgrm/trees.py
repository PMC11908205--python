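"""Succinct tree-sequence data model.

An ancestral recombination graph (ARG) is encoded as a node table (one row
per haploid genome, with a birth time in generations) and an edge table (one
row per inheritance of a genome segment ``[left, right)`` by a child node
from a parent node).  Sweeping edge insertions and removals along the genome
recovers the sequence of *local trees*: the genealogies relating the samples
on each recombination-free interval.

Coordinates are 0-based half-open.  Within each interval the parent
assignment must form a forest; multiple roots (not-fully-coalesced trees)
are permitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeSequence",
    "LocalTree",
    "ValidationError",
    "load_tables",
    "save_tables",
    "iterate_trees",
    "mrca",
    "total_area",
    "remap_coordinates",
    "load_genetic_map",
]

NULL = -1


class ValidationError(ValueError):
    """A table violates a tree-sequence invariant."""


def _as_array(x, dtype):
    a = np.asarray(x, dtype=dtype)
    return np.atleast_1d(a)


@dataclass(frozen=True)
class TreeSequence:
    """Tabular encoding of an ARG.

    Parameters
    ----------
    sequence_length
        Total genome length (right end of the last interval).
    node_time
        Birth time of each node, in generations (non-negative).
    node_is_sample
        Sample flag per node; samples must be leaves for the matrix-free
        product (general statistics only require a non-empty sample set).
    node_individual
        Optional individual index grouping genome copies (-1 = none).
    edge_left, edge_right, edge_parent, edge_child
        One entry per edge; ``[left, right)`` is the inherited segment.
    site_position, mutation_site, mutation_node
        Optional binary (ancestral=0 / derived=1) mutation placement: each
        mutation sits on the branch above ``mutation_node`` at the position
        of its site.
    """

    sequence_length: float
    node_time: np.ndarray
    node_is_sample: np.ndarray
    node_individual: np.ndarray = None  # type: ignore[assignment]
    edge_left: np.ndarray = field(default_factory=lambda: np.empty(0))
    edge_right: np.ndarray = field(default_factory=lambda: np.empty(0))
    edge_parent: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    edge_child: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    site_position: np.ndarray | None = None
    mutation_site: np.ndarray | None = None
    mutation_node: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "node_time", np.asarray(self.node_time, dtype=float))
        object.__setattr__(self, "node_is_sample", np.asarray(self.node_is_sample, dtype=bool))
        if self.node_individual is None:
            object.__setattr__(
                self, "node_individual", np.full(self.num_nodes, NULL, dtype=np.int64)
            )
        else:
            object.__setattr__(
                self, "node_individual", np.asarray(self.node_individual, dtype=np.int64)
            )
        object.__setattr__(self, "edge_left", np.asarray(self.edge_left, dtype=float))
        object.__setattr__(self, "edge_right", np.asarray(self.edge_right, dtype=float))
        object.__setattr__(self, "edge_parent", np.asarray(self.edge_parent, dtype=np.int64))
        object.__setattr__(self, "edge_child", np.asarray(self.edge_child, dtype=np.int64))
        if self.site_position is not None:
            object.__setattr__(self, "site_position", np.asarray(self.site_position, dtype=float))
            object.__setattr__(self, "mutation_site", np.asarray(self.mutation_site, dtype=np.int64))
            object.__setattr__(self, "mutation_node", np.asarray(self.mutation_node, dtype=np.int64))
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def num_nodes(self) -> int:
        return len(self.node_time)

    @property
    def num_edges(self) -> int:
        return len(self.edge_left)

    @property
    def samples(self) -> np.ndarray:
        return np.flatnonzero(self.node_is_sample)

    @property
    def num_samples(self) -> int:
        return int(self.node_is_sample.sum())

    @property
    def num_sites(self) -> int:
        return 0 if self.site_position is None else len(self.site_position)

    @property
    def breakpoints(self) -> np.ndarray:
        """Sorted unique interval boundaries b_0=0 < ... < b_K=L."""
        pts = np.unique(
            np.concatenate([self.edge_left, self.edge_right, [0.0, self.sequence_length]])
        )
        return pts[(pts >= 0) & (pts <= self.sequence_length)]

    @property
    def num_trees(self) -> int:
        return len(self.breakpoints) - 1

    # -- edge event orderings (the sweep contract) -----------------------
    def insertion_order(self) -> np.ndarray:
        """Edges sorted by (left, parent time asc, parent, child)."""
        t = self.node_time[self.edge_parent]
        return np.lexsort((self.edge_child, self.edge_parent, t, self.edge_left))

    def removal_order(self) -> np.ndarray:
        """Edges sorted by (right, parent time desc, parent desc, child desc)."""
        t = self.node_time[self.edge_parent]
        return np.lexsort((-self.edge_child, -self.edge_parent, -t, self.edge_right))

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        L = float(self.sequence_length)
        if not (np.isfinite(L) and L > 0):
            raise ValidationError("sequence_length must be positive and finite")
        t = self.node_time
        if len(t) and (not np.all(np.isfinite(t)) or np.any(t < 0)):
            bad = int(np.flatnonzero(~np.isfinite(t) | (t < 0))[0])
            raise ValidationError(f"node {bad}: time must be finite and >= 0")
        ids = np.concatenate([self.edge_parent, self.edge_child])
        if len(ids) and (ids.min() < 0 or ids.max() >= self.num_nodes):
            raise ValidationError("edge refers to an unknown node index")
        bad = np.flatnonzero(~(self.edge_left < self.edge_right))
        if len(bad):
            raise ValidationError(f"edge {int(bad[0])}: requires left < right")
        bad = np.flatnonzero((self.edge_left < 0) | (self.edge_right > L))
        if len(bad):
            raise ValidationError(f"edge {int(bad[0])}: interval outside [0, sequence_length]")
        bad = np.flatnonzero(
            ~(self.node_time[self.edge_parent] > self.node_time[self.edge_child])
        )
        if len(bad):
            raise ValidationError(
                f"edge {int(bad[0])}: time(parent) must exceed time(child)"
            )
        # per-child disjoint intervals: a genome position has at most one parent
        order = np.lexsort((self.edge_left, self.edge_child))
        c = self.edge_child[order]
        l = self.edge_left[order]
        r = self.edge_right[order]
        same = c[1:] == c[:-1]
        overlap = same & (l[1:] < r[:-1])
        if np.any(overlap):
            i = int(np.flatnonzero(overlap)[0])
            raise ValidationError(
                f"child {int(c[i + 1])}: edges {int(order[i])} and {int(order[i + 1])} "
                "have overlapping intervals"
            )
        if self.site_position is not None:
            p = self.site_position
            if len(p) and (p.min() < 0 or p.max() >= L):
                raise ValidationError("site position outside [0, sequence_length)")
            if len(self.mutation_site) != len(self.mutation_node):
                raise ValidationError("mutation tables have mismatched lengths")
            if len(self.mutation_site) and (
                self.mutation_site.min() < 0 or self.mutation_site.max() >= len(p)
            ):
                raise ValidationError("mutation refers to an unknown site")
        # forest check (no cycles) per interval is implied by parent-time
        # monotonicity plus per-child uniqueness, both enforced above.

    # -- convenience -----------------------------------------------------
    def with_edges(self, left, right, parent, child) -> "TreeSequence":
        return replace(
            self,
            edge_left=np.asarray(left, dtype=float),
            edge_right=np.asarray(right, dtype=float),
            edge_parent=np.asarray(parent, dtype=np.int64),
            edge_child=np.asarray(child, dtype=np.int64),
        )

    def trees(self) -> Iterator["LocalTree"]:
        for tree, _, _ in iterate_trees(self):
            yield tree


@dataclass
class LocalTree:
    """The genealogy on one recombination-free interval ``[left, right)``."""

    left: float
    right: float
    parent: np.ndarray  # per-node parent, NULL = none
    node_time: np.ndarray
    samples: np.ndarray

    @property
    def interval(self) -> tuple[float, float]:
        return (self.left, self.right)

    @property
    def span(self) -> float:
        return self.right - self.left

    def branch_length(self, n: int) -> float:
        """Length of the branch above ``n`` (0 when n has no parent)."""
        p = self.parent[n]
        return 0.0 if p == NULL else float(self.node_time[p] - self.node_time[n])

    def ancestors(self, n: int) -> list[int]:
        """Nodes on the path from ``n`` (inclusive) to its root."""
        path = []
        while n != NULL:
            path.append(int(n))
            n = self.parent[n]
        return path

    def root_of(self, n: int) -> int:
        while self.parent[n] != NULL:
            n = self.parent[n]
        return int(n)

    @property
    def roots(self) -> np.ndarray:
        """Parentless nodes reachable from the sample set."""
        return np.unique([self.root_of(s) for s in self.samples])

    def sample_paths(self) -> tuple[np.ndarray, np.ndarray]:
        """Compact indicator of sample ancestry in this tree.

        Returns ``(nodes, S)`` where ``nodes`` lists every node on a
        sample-to-root path and ``S[a, i] = 1`` iff sample ``i`` descends
        from (or is) ``nodes[a]``.
        """
        index: dict[int, int] = {}
        cols: list[list[int]] = []
        for i, s in enumerate(self.samples):
            n = int(s)
            while n != NULL:
                a = index.get(n)
                if a is None:
                    a = len(cols)
                    index[n] = a
                    cols.append([])
                cols[a].append(i)
                n = self.parent[n]
        nodes = np.fromiter(index.keys(), dtype=np.int64, count=len(index))
        S = np.zeros((len(nodes), len(self.samples)))
        for a, members in enumerate(cols):
            S[a, members] = 1.0
        return nodes, S


def iterate_trees(
    ts: TreeSequence,
) -> Iterator[tuple[LocalTree, np.ndarray, np.ndarray]]:
    """Sweep the genome, yielding ``(tree, removed, added)`` per interval.

    ``removed`` / ``added`` are edge indices applied at the interval's left
    boundary; removals are applied before insertions.  The first interval's
    additions contain every edge covering position 0.
    """
    I = ts.insertion_order()
    O = ts.removal_order()
    E = ts.num_edges
    parent = np.full(ts.num_nodes, NULL, dtype=np.int64)
    samples = ts.samples
    j = k = 0
    left = 0.0
    while left < ts.sequence_length:
        removed = []
        while k < E and ts.edge_right[O[k]] == left:
            e = O[k]
            parent[ts.edge_child[e]] = NULL
            removed.append(e)
            k += 1
        added = []
        while j < E and ts.edge_left[I[j]] == left:
            e = I[j]
            c = ts.edge_child[e]
            if parent[c] != NULL:
                raise ValidationError(
                    f"child {int(c)} acquires two parents at position {left}"
                )
            parent[c] = ts.edge_parent[e]
            added.append(e)
            j += 1
        right = ts.sequence_length
        if j < E:
            right = min(right, ts.edge_left[I[j]])
        if k < E:
            right = min(right, ts.edge_right[O[k]])
        tree = LocalTree(
            left=float(left),
            right=float(right),
            parent=parent.copy(),
            node_time=ts.node_time,
            samples=samples,
        )
        # no explicit cycle guard: time(parent) > time(child) on every edge
        # (enforced at validation) makes cycles impossible; the two-parents
        # check above catches the remaining inconsistency mode.
        yield tree, np.asarray(removed, dtype=np.int64), np.asarray(added, dtype=np.int64)
        left = right


def mrca(tree: LocalTree, u: int, v: int) -> int | None:
    """Most recent common ancestor of ``u`` and ``v``, or ``None`` when the
    two lie in different root-subtrees."""
    n = tree.parent.shape[0]
    if not (0 <= u < n and 0 <= v < n):
        raise ValueError(f"unknown node index: {u if not 0 <= u < n else v}")
    anc = set(tree.ancestors(u))
    m = int(v)
    while m != NULL:
        if m in anc:
            return m
        m = tree.parent[m]
    return None


def total_area(ts: TreeSequence) -> float:
    """Total ARG area: sum over trees and branches of span x branch length,
    counting only branches ancestral to at least one sample."""
    area = 0.0
    for tree in ts.trees():
        nodes, _ = tree.sample_paths()
        area += tree.span * sum(tree.branch_length(n) for n in nodes)
    return area


def remap_coordinates(
    ts: TreeSequence, genetic_map: Sequence[tuple[float, float]]
) -> TreeSequence:
    """Remap genome coordinates (e.g. base pairs -> genetic distance) by
    piecewise-linear interpolation.  Node times are unchanged."""
    gm = np.asarray(genetic_map, dtype=float)
    if gm.ndim != 2 or gm.shape[1] != 2 or gm.shape[0] < 2:
        raise ValueError("genetic map must be a list of (physical, genetic) pairs")
    phys, gen = gm[:, 0], gm[:, 1]
    if np.any(np.diff(phys) <= 0) or np.any(np.diff(gen) <= 0):
        raise ValueError("genetic map must be strictly increasing in both columns")
    if phys[0] > 0 or phys[-1] < ts.sequence_length:
        raise ValueError("genetic map must cover [0, sequence_length]")

    def f(x):
        return np.interp(x, phys, gen)

    new = replace(
        ts,
        sequence_length=float(f(ts.sequence_length)),
        edge_left=f(ts.edge_left),
        edge_right=f(ts.edge_right),
        site_position=None if ts.site_position is None else f(ts.site_position),
    )
    return new


# ---------------------------------------------------------------------------
# Table I/O (tab-separated text dialect)
# ---------------------------------------------------------------------------

def load_tables(
    nodes_path,
    edges_path,
    sites_path=None,
    mutations_path=None,
    sequence_length: float | None = None,
) -> TreeSequence:
    """Load a tree sequence from TSV tables.

    ``nodes.tsv``: columns id, time, is_sample, individual.
    ``edges.tsv``: columns left, right, parent, child.
    ``sites.tsv``: column position; ``mutations.tsv``: columns site, node.
    When ``sequence_length`` is omitted it defaults to max(edge right).
    """
    try:
        nodes = pd.read_csv(nodes_path, sep="\t", float_precision="round_trip")
        edges = pd.read_csv(edges_path, sep="\t", float_precision="round_trip")
    except Exception as err:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"could not parse tables: {err}") from err
    for col in ("id", "time", "is_sample"):
        if col not in nodes.columns:
            raise ValidationError(f"nodes table lacks required column '{col}'")
    for col in ("left", "right", "parent", "child"):
        if col not in edges.columns:
            raise ValidationError(f"edges table lacks required column '{col}'")
    nodes = nodes.sort_values("id").reset_index(drop=True)
    if not np.array_equal(nodes["id"].to_numpy(), np.arange(len(nodes))):
        raise ValidationError("node ids must be exactly 0..n-1")
    if sequence_length is None:
        if len(edges) == 0:
            raise ValidationError("cannot infer sequence_length from an empty edge table")
        sequence_length = float(edges["right"].max())
    site_position = mutation_site = mutation_node = None
    if sites_path is not None:
        sites = pd.read_csv(sites_path, sep="\t", float_precision="round_trip")
        site_position = sites["position"].to_numpy(dtype=float)
        if mutations_path is not None:
            muts = pd.read_csv(mutations_path, sep="\t")
            mutation_site = muts["site"].to_numpy(dtype=np.int64)
            mutation_node = muts["node"].to_numpy(dtype=np.int64)
        else:
            mutation_site = np.empty(0, dtype=np.int64)
            mutation_node = np.empty(0, dtype=np.int64)
    return TreeSequence(
        sequence_length=sequence_length,
        node_time=nodes["time"].to_numpy(dtype=float),
        node_is_sample=nodes["is_sample"].to_numpy(dtype=bool),
        node_individual=(
            nodes["individual"].to_numpy(dtype=np.int64)
            if "individual" in nodes.columns
            else None
        ),
        edge_left=edges["left"].to_numpy(dtype=float),
        edge_right=edges["right"].to_numpy(dtype=float),
        edge_parent=edges["parent"].to_numpy(dtype=np.int64),
        edge_child=edges["child"].to_numpy(dtype=np.int64),
        site_position=site_position,
        mutation_site=mutation_site,
        mutation_node=mutation_node,
    )


def save_tables(ts: TreeSequence, prefix: str) -> list[str]:
    """Write ``<prefix>.nodes.tsv`` / ``.edges.tsv`` (and site/mutation
    tables when present) with full floating-point precision."""
    written = []
    nodes = pd.DataFrame(
        {
            "id": np.arange(ts.num_nodes),
            "time": ts.node_time,
            "is_sample": ts.node_is_sample.astype(int),
            "individual": ts.node_individual,
        }
    )
    path = f"{prefix}.nodes.tsv"
    nodes.to_csv(path, sep="\t", index=False, float_format="%.17g")
    written.append(path)
    edges = pd.DataFrame(
        {
            "left": ts.edge_left,
            "right": ts.edge_right,
            "parent": ts.edge_parent,
            "child": ts.edge_child,
        }
    )
    path = f"{prefix}.edges.tsv"
    edges.to_csv(path, sep="\t", index=False, float_format="%.17g")
    written.append(path)
    if ts.site_position is not None:
        path = f"{prefix}.sites.tsv"
        pd.DataFrame({"position": ts.site_position}).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
        written.append(path)
        path = f"{prefix}.mutations.tsv"
        pd.DataFrame({"site": ts.mutation_site, "node": ts.mutation_node}).to_csv(
            path, sep="\t", index=False
        )
        written.append(path)
    return written


def load_genetic_map(path) -> np.ndarray:
    """Read a 2-column (physical, genetic) TSV, strictly increasing."""
    gm = pd.read_csv(path, sep="\t", float_precision="round_trip").to_numpy(dtype=float)
    if gm.shape[1] != 2:
        raise ValueError("genetic map must have exactly two columns")
    return gm
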