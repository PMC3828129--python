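"""Independent brute-force oracles used by the test suite.

These deliberately avoid the dynamic-programming code paths they check:
parsimony costs come from exhaustive enumeration of all internal-node
state assignments, MRCAs from naive pairwise ancestor reduction.
"""

import numpy as np

from foldspace.trees import node_id


def enumerate_scenarios(tree, profile, g, euk_nodes=None, euk_cap=1):
    """Exhaustive gain/loss parsimony by enumerating internal states.

    Returns (min_cost, max_age_among_optimal, min_age_among_optimal).
    The hypothetical ancestor above the root is absent, so a present
    root incurs one gain at the root.  With ``euk_nodes`` given, only
    assignments with at most ``euk_cap`` gains at those nodes count.
    """
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): k for k, nd in enumerate(nodes)}
    internal = [k for k, nd in enumerate(nodes) if not nd.is_leaf()]
    n_nodes = len(nodes)
    n_int = len(internal)
    n_assign = 2**n_int
    states = np.zeros((n_assign, n_nodes), dtype=np.int8)
    for bit, col in enumerate(internal):
        states[:, col] = (np.arange(n_assign) >> bit) & 1
    for k, nd in enumerate(nodes):
        if nd.is_leaf():
            states[:, k] = profile[nd.taxon.label]

    ages = np.array([nd.age for nd in nodes])
    edges = [
        (index[id(nd.parent_node)], k)
        for k, nd in enumerate(nodes)
        if nd.parent_node is not None
    ]
    p_idx = np.array([e[0] for e in edges])
    c_idx = np.array([e[1] for e in edges])
    P = states[:, p_idx]
    C = states[:, c_idx]
    gain_edges = (P == 0) & (C == 1)
    loss_edges = (P == 1) & (C == 0)
    root_col = index[id(tree.seed_node)]
    root_gain = states[:, root_col] == 1
    cost = g * (gain_edges.sum(axis=1) + root_gain) + loss_edges.sum(axis=1)

    if euk_nodes is not None:
        euk_edge = np.array([id(nodes[c]) in euk_nodes for c in c_idx])
        euk_gains = gain_edges[:, euk_edge].sum(axis=1)
        if id(tree.seed_node) in euk_nodes:
            euk_gains = euk_gains + root_gain
        feasible = euk_gains <= euk_cap
    else:
        feasible = np.ones(n_assign, dtype=bool)

    cost = np.where(feasible, cost, np.inf)
    min_cost = cost.min()
    optimal = np.isclose(cost, min_cost)

    gain_age = np.where(gain_edges, ages[c_idx][None, :], -1.0)
    max_gain_age = gain_age.max(axis=1)
    max_gain_age = np.where(
        root_gain, np.maximum(max_gain_age, ages[root_col]), max_gain_age
    )
    has_gain = (gain_edges.any(axis=1)) | root_gain
    opt_ages = max_gain_age[optimal & has_gain]
    best_old = opt_ages.max() if len(opt_ages) else None
    best_young = opt_ages.min() if len(opt_ages) else None
    return float(min_cost), best_old, best_young


def naive_mrca_age(tree, profile):
    """MRCA age of present leaves by pairwise ancestor-set reduction."""
    present = [
        lf for lf in tree.leaf_node_iter() if profile[lf.taxon.label] == 1
    ]
    common = None
    for lf in present:
        anc = []
        nd = lf
        while nd is not None:
            anc.append(id(nd))
            nd = nd.parent_node
        if common is None:
            common = anc
        else:
            keep = set(anc)
            common = [a for a in common if a in keep]
    by_id = {id(nd): nd for nd in tree.preorder_node_iter()}
    return by_id[common[0]].age, node_id(by_id[common[0]])


def random_profile(tree, rng, p=0.5):
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    prof = {l: int(rng.random() < p) for l in labels}
    if sum(prof.values()) == 0:
        prof[labels[int(rng.integers(len(labels)))]] = 1
    return prof
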