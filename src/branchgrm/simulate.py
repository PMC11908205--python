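"""Synthetic-data generators.

Everything the relatedness machinery consumes can be generated here at
desk scale: coalescent-with-recombination tree sequences (a sequential,
SMC-style generator), Poisson mutation dropping, additive traits, random
pedigrees, gene-dropping of chromosomes through a fixed pedigree, and
coalescent completion ("recapitation") of the open founder lineages.

Scales follow the neutral coalescent: with haploid effective size N_e the
pair-coalescence rate is 1/N_e per generation, so the expected pairwise
TMRCA is N_e generations.  Recombination is a Poisson process of rate
``recombination_rate`` per unit genome length per generation, so breakpoints
arrive along the genome at rate rho x (total branch length).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pedigree import NULL, Pedigree
from .trees import TreeSequence

__all__ = [
    "SimulationConfig",
    "TraitModel",
    "simulate_coalescent_ts",
    "drop_mutations",
    "genotypes_from_mutations",
    "simulate_trait",
    "gene_drop",
    "recapitate",
    "mean_tmrca",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a neutral coalescent-with-recombination simulation.

    ``effective_size`` is the *haploid* N_e; ``recombination_rate`` is per
    unit genome length per generation; ``mutation_rate`` is per unit of
    branch area (length x span).
    """

    n_samples: int = 16
    sequence_length: float = 1.0
    effective_size: float = 1.0
    recombination_rate: float = 1.0
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        if min(self.sequence_length, self.effective_size) <= 0:
            raise ValueError("sequence_length and effective_size must be positive")
        if min(self.recombination_rate, self.mutation_rate) < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class TraitModel:
    """An additive trait realization: i.i.d. Normal(0, sigma2) effects per
    site, genetic values Z = G @ effects, and their sample mean."""

    sigma2: float
    effects: np.ndarray
    Z: np.ndarray

    @property
    def Z_bar(self) -> float:
        return float(self.Z.mean())


# ---------------------------------------------------------------------------
# sequential coalescent-with-recombination generator
# ---------------------------------------------------------------------------

def simulate_coalescent_ts(
    cfg: SimulationConfig, max_trees: int | None = None
) -> TreeSequence:
    """Simulate a tree sequence under a sequential (SMC-style) coalescent.

    The leftmost tree is drawn from the Kingman coalescent (pair rate
    1/N_e).  Moving right, recombination breakpoints arrive at genomic rate
    rho x total branch length; at each one a point is chosen uniformly on
    the branches, the lineage above it is erased up to the next coalescent
    node, and the detached subtree re-coalesces into the remaining tree.
    This is the classic SMC approximation: marginal trees are
    coalescent-distributed, while correlations between distant trees are
    slightly simplified.  ``max_trees`` optionally stops adding breakpoints
    after that many local trees (the last tree then extends to the end).
    """
    rng = _rng(cfg.seed)
    n = cfg.n_samples
    Ne = float(cfg.effective_size)
    L = float(cfg.sequence_length)
    rho = float(cfg.recombination_rate)

    times: list[float] = [0.0] * n
    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {}

    def new_node(t: float) -> int:
        times.append(t)
        return len(times) - 1

    # leftmost tree: Kingman coalescent
    active = list(range(n))
    t = 0.0
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(Ne / (j * (j - 1) / 2.0))
        i1, i2 = sorted(map(int, rng.choice(j, size=2, replace=False)))
        a, b = active[i1], active[i2]
        v = new_node(t)
        parent[a] = v
        parent[b] = v
        children[v] = [a, b]
        active[i1] = v
        active[i2] = active[-1]
        active.pop()
    root = active[0]

    edges: list[tuple[float, float, int, int]] = []
    open_left: dict[int, float] = {c: 0.0 for c in parent}

    def detach(c: int, pos: float) -> None:
        p = parent.pop(c)
        left = open_left.pop(c)
        if left < pos:
            edges.append((left, pos, p, c))
        children[p].remove(c)

    def attach(c: int, p: int, pos: float) -> None:
        parent[c] = p
        children.setdefault(p, []).append(c)
        open_left[c] = pos

    x = 0.0
    n_trees = 1
    while True:
        if max_trees is not None and n_trees >= max_trees:
            break
        branch_nodes = list(parent.keys())
        lengths = np.array([times[parent[c]] - times[c] for c in branch_nodes])
        total = lengths.sum()
        if rho * total <= 0:
            break
        x_new = x + rng.exponential(1.0 / (rho * total))
        if x_new >= L:
            break
        x = x_new
        n_trees += 1
        # choose the cut point uniformly on the branches
        ci = rng.choice(len(branch_nodes), p=lengths / total)
        c = branch_nodes[int(ci)]
        p = parent[c]
        u = rng.uniform(times[c], times[p])
        # prune: erase the lineage from the cut up to its coalescent node p
        sibs = [d for d in children[p] if d != c]
        detach(c, x)
        if len(sibs) == 1:
            d = sibs[0]
            q = parent.get(p)
            detach(d, x)
            if q is None:
                root = d
            else:
                detach(p, x)
                attach(d, q, x)
        # re-coalesce the floating lineage (carrying c, from time u)
        t_star, e = _recoalesce(children, times, root, u, Ne, rng)
        v = new_node(t_star)
        q2 = parent.get(e)
        if q2 is not None:
            detach(e, x)
            attach(v, q2, x)
        else:
            root = v
        attach(e, v, x)
        attach(c, v, x)
    for c in list(parent):
        detach(c, L)
    ts = TreeSequence(
        sequence_length=L,
        node_time=np.asarray(times),
        node_is_sample=np.arange(len(times)) < n,
        edge_left=[e[0] for e in edges],
        edge_right=[e[1] for e in edges],
        edge_parent=[e[2] for e in edges],
        edge_child=[e[3] for e in edges],
    )
    return ts


def _recoalesce(children, times, root, u, Ne, rng):
    """Sample the time and partner branch at which a floating lineage
    (alive from time ``u`` backwards) joins the remaining tree.

    Lineages of the remaining tree are its branches (collected by
    traversal from the root, which excludes the floating subtree), each
    alive on [t_child, t_parent), plus the root lineage alive on
    [t_root, inf).  The floating lineage coalesces at rate k(tau)/N_e with
    k(tau) the number of lineages alive at tau, choosing a partner
    uniformly among those alive at the sampled time.
    """
    intervals = []
    stack = [root]
    while stack:
        node = stack.pop()
        for ch in children.get(node, []):
            intervals.append((times[ch], times[node], ch))
            stack.append(ch)
    intervals.append((times[root], np.inf, root))
    pts = sorted(
        {u}
        | {lo for lo, hi, _ in intervals if lo > u}
        | {hi for lo, hi, _ in intervals if u < hi < np.inf}
    )
    tau = u
    for nxt in pts[1:] + [np.inf]:
        k = sum(1 for lo, hi, _ in intervals if lo <= tau < hi)
        if k > 0:
            wait = rng.exponential(Ne / k)
            if tau + wait < nxt:
                t_star = tau + wait
                alive = [c for lo, hi, c in intervals if lo <= t_star < hi]
                return t_star, alive[int(rng.integers(len(alive)))]
        tau = nxt
    raise AssertionError("root lineage extends to infinity; unreachable")


# ---------------------------------------------------------------------------
# mutations, genotypes, traits
# ---------------------------------------------------------------------------

def drop_mutations(ts: TreeSequence, mu: float, seed) -> TreeSequence:
    """Drop binary mutations as a Poisson process of rate ``mu`` per unit
    of branch area; each mutation founds a new site at a uniform position
    on its local tree's interval, on the branch above its node."""
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    rng = _rng(seed)
    positions: list[np.ndarray] = []
    nodes: list[np.ndarray] = []
    for tree in ts.trees():
        tnodes, _ = tree.sample_paths()
        ell = np.array([tree.branch_length(n_) for n_ in tnodes])
        counts = rng.poisson(mu * tree.span * ell)
        total = int(counts.sum())
        if total == 0:
            continue
        positions.append(rng.uniform(tree.left, tree.right, size=total))
        nodes.append(np.repeat(tnodes, counts))
    if positions:
        pos = np.concatenate(positions)
        nod = np.concatenate(nodes)
        order = np.argsort(pos, kind="stable")
        pos, nod = pos[order], nod[order]
    else:
        pos = np.empty(0)
        nod = np.empty(0, dtype=np.int64)
    return replace(
        ts,
        site_position=pos,
        mutation_site=np.arange(len(pos), dtype=np.int64),
        mutation_node=nod,
    )


def genotypes_from_mutations(ts: TreeSequence) -> np.ndarray:
    """Binary genotype matrix (samples x sites); entry 1 means the sample
    inherits the derived allele (descends from the mutation's node in the
    local tree covering the site)."""
    if ts.site_position is None:
        raise ValueError("tree sequence carries no mutations")
    n = ts.num_samples
    m = ts.num_sites
    G = np.zeros((n, m))
    if m == 0:
        return G
    site_node = np.full(m, NULL, dtype=np.int64)
    site_node[ts.mutation_site] = ts.mutation_node
    for tree in ts.trees():
        here = np.flatnonzero(
            (ts.site_position >= tree.left) & (ts.site_position < tree.right)
        )
        if len(here) == 0:
            continue
        tnodes, S = tree.sample_paths()
        index = {int(n_): a for a, n_ in enumerate(tnodes)}
        for s_ in here:
            a = index.get(int(site_node[s_]))
            if a is not None:
                G[:, s_] = S[a]
    return G


def simulate_trait(G: np.ndarray, sigma2: float, seed) -> TraitModel:
    """Draw i.i.d. Normal(0, sigma2) per-site effects and return the
    additive genetic values Z = G @ effects (haploid convention)."""
    G = np.asarray(G, dtype=float)
    rng = _rng(seed)
    effects = rng.normal(0.0, np.sqrt(sigma2), size=G.shape[1])
    return TraitModel(sigma2=float(sigma2), effects=effects, Z=G @ effects)


# ---------------------------------------------------------------------------
# gene-dropping through a pedigree & recapitation
# ---------------------------------------------------------------------------

def gene_drop(
    ped: Pedigree, sequence_length: float, recombination_rate: float, seed
) -> TreeSequence:
    """Simulate Mendelian inheritance with recombination through a fixed
    pedigree.

    Each individual contributes two genome-copy nodes (individual index
    recorded on the node); each non-founder copy is a recombination mosaic
    of its parent's two copies, with Poisson(rho x L) breakpoints per
    meiosis.  Probands' copies are flagged as samples; founder copies are
    the roots of every local tree (their ancestry is left open for
    :func:`recapitate`).  Node times are generations before the probands.
    """
    rng = _rng(seed)
    n_ind = ped.num_individuals
    g_max = int(ped.generation.max())
    node_time = np.repeat(g_max - ped.generation, 2).astype(float)
    node_individual = np.repeat(np.arange(n_ind), 2)
    is_sample = np.repeat(ped.is_proband, 2)
    L = float(sequence_length)

    left: list[float] = []
    right: list[float] = []
    par: list[int] = []
    chi: list[int] = []

    def copy_id(ind: int, which: int) -> int:
        return 2 * ind + which

    for i in range(n_ind):
        for which, parent_ind in ((0, ped.father[i]), (1, ped.mother[i])):
            if parent_ind == NULL:
                continue  # founder copy: open root
            child = copy_id(i, which)
            k = rng.poisson(recombination_rate * L)
            cuts = np.sort(rng.uniform(0.0, L, size=k)) if k else np.empty(0)
            bounds = np.concatenate([[0.0], cuts, [L]])
            phase = int(rng.integers(2))
            for s_ in range(len(bounds) - 1):
                lo, hi = bounds[s_], bounds[s_ + 1]
                if lo == hi:
                    continue
                left.append(lo)
                right.append(hi)
                par.append(copy_id(int(parent_ind), (phase + s_) % 2))
                chi.append(child)
    return TreeSequence(
        sequence_length=L,
        node_time=node_time,
        node_is_sample=is_sample,
        node_individual=node_individual,
        edge_left=np.asarray(left),
        edge_right=np.asarray(right),
        edge_parent=np.asarray(par, dtype=np.int64),
        edge_child=np.asarray(chi, dtype=np.int64),
    )


def recapitate(ts: TreeSequence, effective_size: float, seed) -> TreeSequence:
    """Coalesce the open root lineages of every local tree under a Kingman
    coalescent with haploid size ``effective_size``.

    Each local tree is completed *independently* (linkage between founder
    lineages across neighbouring trees is ignored).  This preserves the
    marginal distribution of each local tree, which is what the pedigree
    comparisons use, but deliberately simplifies cross-tree covariance;
    see the methods note.
    """
    rng = _rng(seed)
    Ne = float(effective_size)
    times = list(ts.node_time)
    new_left: list[float] = []
    new_right: list[float] = []
    new_par: list[int] = []
    new_chi: list[int] = []
    for tree in ts.trees():
        roots = [int(r) for r in tree.roots]
        if len(roots) <= 1:
            continue
        pending = sorted(roots, key=lambda r: times[r])
        active: list[int] = []
        tau = times[pending[0]]
        while len(active) + len(pending) > 1:
            while pending and times[pending[0]] <= tau:
                active.append(pending.pop(0))
            if len(active) < 2:
                tau = times[pending[0]]
                continue
            j = len(active)
            wait = rng.exponential(Ne / (j * (j - 1) / 2.0))
            if pending and tau + wait > times[pending[0]]:
                tau = times[pending[0]]
                continue
            tau += wait
            a, b = rng.choice(j, size=2, replace=False)
            a, b = active[int(a)], active[int(b)]
            times.append(tau)
            v = len(times) - 1
            for child in (a, b):
                new_left.append(tree.left)
                new_right.append(tree.right)
                new_par.append(v)
                new_chi.append(child)
            active = [x for x in active if x not in (a, b)] + [v]
    n_new = len(times) - ts.num_nodes
    return replace(
        ts,
        node_time=np.asarray(times),
        node_is_sample=np.concatenate([ts.node_is_sample, np.zeros(n_new, dtype=bool)]),
        node_individual=np.concatenate(
            [ts.node_individual, np.full(n_new, NULL, dtype=np.int64)]
        ),
        edge_left=np.concatenate([ts.edge_left, new_left]),
        edge_right=np.concatenate([ts.edge_right, new_right]),
        edge_parent=np.concatenate([ts.edge_parent, np.asarray(new_par, dtype=np.int64)]),
        edge_child=np.concatenate([ts.edge_child, np.asarray(new_chi, dtype=np.int64)]),
    )


def mean_tmrca(ts: TreeSequence) -> float:
    """Mean pairwise TMRCA: the average over sample pairs of
    D(i, j) / (2 L), computed from the exact branch identity
    D = R_i + R_j - 2 A(i, j) (requires a fully coalesced sequence)."""
    from .relatedness import _shared_area_and_roots

    C, R, same_root = _shared_area_and_roots(ts)
    if not same_root.all():
        raise ValueError("mean TMRCA requires a fully coalesced tree sequence")
    n = len(R)
    if n < 2:
        raise ValueError("need at least two samples")
    D = R[:, None] + R[None, :] - 2.0 * C
    off = ~np.eye(n, dtype=bool)
    return float(D[off].mean() / (2.0 * ts.sequence_length))
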