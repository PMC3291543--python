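"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the library paths they check:
minimum change counts come from exhaustive enumeration of all internal
labelings, clustering checks from direct pairwise criteria.
"""

from __future__ import annotations

from itertools import product


def brute_force_min_changes(tree) -> int:
    """Exhaustive-minimum number of state changes on a rooted tree whose
    leaves carry state *sets* (any member satisfiable at no cost).

    Enumerates every assignment of a state (from the union of leaf
    states) to every internal node; leaf edges cost 0 iff the leaf's set
    contains its parent's state.
    """
    leaf_sets = {}
    internal_ids = []
    parent_of = {}
    for node in tree.preorder():
        nid = tree.node_id(node)
        if node.parent_node is not None:
            parent_of[nid] = tree.node_id(node.parent_node)
        if node.is_leaf():
            leaf_sets[nid] = tree.leaf_record(nid).ec_set
        else:
            internal_ids.append(nid)
    states = sorted(
        {s for ss in leaf_sets.values() for s in ss}, key=lambda s: s.sort_key()
    )
    internal_edges = [
        (parent_of[nid], nid) for nid in internal_ids if nid in parent_of
    ]
    best = None
    for labels in product(states, repeat=len(internal_ids)):
        assign = dict(zip(internal_ids, labels))
        cost = sum(1 for p, c in internal_edges if assign[p] != assign[c])
        for lid, options in leaf_sets.items():
            if assign[parent_of[lid]] not in options:
                cost += 1
        if best is None or cost < best:
            best = cost
            if best == 0:
                break
    return best


def random_binary_newick(n_leaves: int, rng) -> str:
    """Uniform-split random binary topology with leaves x0..x{n-1}."""
    nodes = [f"x{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(0, len(nodes)))
        b = nodes.pop(j)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def enumerate_contiguous_subs(domains):
    """All contiguous ordered runs of a domain list, as strings."""
    out = set()
    for i in range(len(domains)):
        for j in range(i + 1, len(domains) + 1):
            out.add("-".join(domains[i:j]))
    return out
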