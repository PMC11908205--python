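"""Adapters to and from the binary succinct tree-sequence format.

Used for cross-validation against the reference tskit library and for
importing externally simulated ARGs; the native text tables in
:mod:`branchgrm.trees` remain the package's own format.  tskit is imported
lazily so the core package does not depend on it.
"""

from __future__ import annotations

import numpy as np

from .trees import NULL, TreeSequence

__all__ = ["to_tskit", "from_tskit"]


def to_tskit(ts: TreeSequence):
    import tskit

    t = tskit.TableCollection(sequence_length=ts.sequence_length)
    individuals = {}
    for i in sorted(set(ts.node_individual) - {NULL}):
        individuals[i] = t.individuals.add_row()
    for i in range(ts.num_nodes):
        t.nodes.add_row(
            flags=tskit.NODE_IS_SAMPLE if ts.node_is_sample[i] else 0,
            time=float(ts.node_time[i]),
            individual=individuals.get(int(ts.node_individual[i]), -1),
        )
    for e in range(ts.num_edges):
        t.edges.add_row(
            float(ts.edge_left[e]),
            float(ts.edge_right[e]),
            int(ts.edge_parent[e]),
            int(ts.edge_child[e]),
        )
    if ts.site_position is not None:
        for p in ts.site_position:
            t.sites.add_row(position=float(p), ancestral_state="0")
        for s, n in zip(ts.mutation_site, ts.mutation_node):
            t.mutations.add_row(site=int(s), node=int(n), derived_state="1")
    t.sort()
    t.build_index()
    return t.tree_sequence()


def from_tskit(tts) -> TreeSequence:
    tab = tts.tables
    individual = np.asarray(tab.nodes.individual, dtype=np.int64)
    site_position = mutation_site = mutation_node = None
    if tts.num_sites:
        site_position = np.asarray(tab.sites.position, dtype=float)
        mutation_site = np.asarray(tab.mutations.site, dtype=np.int64)
        mutation_node = np.asarray(tab.mutations.node, dtype=np.int64)
    return TreeSequence(
        sequence_length=float(tts.sequence_length),
        node_time=np.asarray(tab.nodes.time, dtype=float),
        node_is_sample=np.asarray(tab.nodes.flags & 1, dtype=bool),
        node_individual=individual,
        edge_left=np.asarray(tab.edges.left, dtype=float),
        edge_right=np.asarray(tab.edges.right, dtype=float),
        edge_parent=np.asarray(tab.edges.parent, dtype=np.int64),
        edge_child=np.asarray(tab.edges.child, dtype=np.int64),
        site_position=site_position,
        mutation_site=mutation_site,
        mutation_node=mutation_node,
    )
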