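"""Species-tree construction for age estimation.

Builds whole-genome trees from binary occurrence profiles: neighbour
joining on Jaccard / Bray-Curtis distances, delete-half jackknife
resampling with extended majority-rule consensus, Fitch-Margoliash style
weighted least-squares branch lengths, Wagner-parsimony branch lengths on
a fixed topology, rooting at the superkingdom trifurcation or on an
outgroup, and normalization of node heights to relative ages in [0, 1]
(0 at the leaves, 1 at the root).

Trees are :class:`dendropy.Tree` objects.  Leaves are identified by their
taxon label; internal nodes receive stable ``N<k>`` labels assigned in
preorder by :func:`label_internal_nodes`.  :func:`normalize_heights`
stores the relative age of every node on the ``age`` attribute.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import dendropy
import numpy as np
import skbio
from scipy.optimize import lsq_linear

from foldspace.occurrence import DistanceMatrix, OccurrenceMatrix

logger = logging.getLogger(__name__)

_INF = float("inf")


# ---------------------------------------------------------------------------
# node bookkeeping


def node_id(node: dendropy.Node) -> str:
    """Stable identifier of a node: taxon label for leaves, node label else."""
    if node.taxon is not None:
        return node.taxon.label
    if node.label is None:
        raise ValueError("internal node has no label; call label_internal_nodes")
    return node.label


def label_internal_nodes(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign deterministic ``N<k>`` preorder labels to unlabeled internal nodes."""
    k = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None and node.label is None:
            node.label = f"N{k}"
        k += 1
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def read_newick(source: str, from_path: bool = False) -> dendropy.Tree:
    kwargs = {"path": source} if from_path else {"data": source}
    tree = dendropy.Tree.get(schema="newick", preserve_underscores=True, **kwargs)
    return label_internal_nodes(tree)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# neighbour joining


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Neighbour-joining tree from a genome dissimilarity matrix.

    Negative branch-length estimates are clamped to zero.  The returned
    tree is unrooted (trifurcating seed node).
    """
    ids = D.genome_ids
    if len(ids) < 4:
        raise ValueError(
            "neighbour joining needs >= 4 taxa; build the tree directly instead"
        )
    dm = skbio.DistanceMatrix(D.df.to_numpy(dtype=float), ids=ids)
    newick = str(skbio.tree.nj(dm, neg_as_zero=True))
    tree = read_newick(newick)
    tree.is_rooted = False
    return tree


def jackknife_samples(
    m: OccurrenceMatrix,
    n_samples: int = 100,
    fraction: float = 0.5,
    seed: int = 1,
) -> list[OccurrenceMatrix]:
    """Delete-half jackknife resamples of the units of an occurrence matrix.

    Each sample keeps ``floor(fraction * U)`` units drawn without
    replacement; resampling is over units, not genomes.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    units = m.unit_ids
    if len(units) < 2:
        raise ValueError("need at least 2 units to resample")
    keep = int(math.floor(fraction * len(units)))
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_samples):
        chosen = rng.choice(len(units), size=keep, replace=False)
        chosen.sort()
        samples.append(
            OccurrenceMatrix(df=m.df.iloc[chosen].copy(), level=m.level)
        )
    return samples


# ---------------------------------------------------------------------------
# consensus


def _split_frequencies(trees: Sequence[dendropy.Tree]):
    """Frequencies of non-trivial unrooted splits across an ensemble."""
    tns = trees[0].taxon_namespace
    leafsets = [set(leaf_labels(t)) for t in trees]
    if any(ls != leafsets[0] for ls in leafsets):
        raise ValueError("ensemble trees must share one leaf set")
    n_taxa = len(leafsets[0])
    full = tns.all_taxa_bitmask()
    counts: dict[int, int] = {}
    for t in trees:
        if t.taxon_namespace is not tns:
            raise ValueError("ensemble trees must share a taxon namespace")
        t.encode_bipartitions()
        seen = set()
        for b in t.bipartition_encoding:
            mask = b.split_bitmask
            norm = min(mask & full, (~mask) & full)
            size = bin(norm).count("1")
            if size < 2 or size > n_taxa - 2:
                continue  # trivial split
            seen.add(norm)
        for s in seen:
            counts[s] = counts.get(s, 0) + 1
    return counts, tns, full


def _compatible(s1: int, s2: int, full: int) -> bool:
    return (
        s1 & s2 == 0
        or s1 & (~s2 & full) == 0
        or (~s1 & full) & s2 == 0
        or (~s1 & full) & (~s2 & full) == 0
    )


def majority_rule_consensus(
    trees: Sequence[dendropy.Tree], extended: bool = True
) -> dendropy.Tree:
    """(Extended) majority-rule consensus topology of a tree ensemble.

    Splits occurring in more than half the trees are always included; with
    ``extended=True`` the remaining splits are added greedily in order of
    decreasing frequency whenever compatible with the accepted set, as in
    PHYLIP's CONSENSE.  Branch lengths are not assigned.
    """
    if not trees:
        raise ValueError("empty ensemble")
    counts, tns, full = _split_frequencies(trees)
    n = len(trees)
    accepted: list[int] = []
    # deterministic order: frequency desc, then bitmask
    for mask, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if cnt / n > 0.5:
            accepted.append(mask)
        elif extended and all(_compatible(mask, a, full) for a in accepted):
            accepted.append(mask)
    tree = dendropy.Tree.from_split_bitmasks(accepted, tns, is_rooted=False)
    return label_internal_nodes(tree)


def split_support(trees: Sequence[dendropy.Tree]) -> dict[int, float]:
    """Per-split frequency (support) across an ensemble, keyed by bitmask."""
    counts, _tns, _full = _split_frequencies(trees)
    n = len(trees)
    return {mask: cnt / n for mask, cnt in counts.items()}


# ---------------------------------------------------------------------------
# branch lengths


def _edges_with_parent(tree: dendropy.Tree) -> list[dendropy.Edge]:
    return [nd.edge for nd in tree.preorder_node_iter() if nd.parent_node is not None]


def fit_branch_lengths_ls(
    topology: dendropy.Tree, D: DistanceMatrix
) -> dendropy.Tree:
    """Weighted least-squares (Fitch-Margoliash) branch lengths on a topology.

    Minimizes sum_ij w_ij (d_ij - p_ij)^2 with w_ij = 1/d_ij^2 subject to
    non-negative branch lengths; zero distances fall back to the largest
    finite weight.  The topology is modified in place and returned.
    """
    tree = topology
    label_internal_nodes(tree)
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    ids = D.genome_ids
    if set(leaves) != set(ids):
        raise ValueError("topology leaf set must equal distance-matrix taxa")
    edges = _edges_with_parent(tree)
    edge_index = {id(e): k for k, e in enumerate(edges)}

    # edge sets on root paths, as index sets
    path_to_root: dict[str, frozenset[int]] = {}
    for lab, lf in leaves.items():
        idxs = set()
        nd = lf
        while nd.parent_node is not None:
            idxs.add(edge_index[id(nd.edge)])
            nd = nd.parent_node
        path_to_root[lab] = frozenset(idxs)

    pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        sym = path_to_root[ids[i]] ^ path_to_root[ids[j]]
        A[row, list(sym)] = 1.0
        d[row] = D.df.iloc[i, j]
    with np.errstate(divide="ignore"):
        w = 1.0 / np.square(d)
    finite = np.isfinite(w)
    if not finite.any():
        w = np.ones_like(w)
    else:
        w[~finite] = w[finite].max()
    sw = np.sqrt(w)
    res = lsq_linear(A * sw[:, None], d * sw, bounds=(0.0, np.inf))
    for e, ln in zip(edges, res.x):
        e.length = max(float(ln), 0.0)
    return tree


def _profile_vector(profile: Mapping[str, int], tree: dendropy.Tree) -> dict[str, int]:
    labels = leaf_labels(tree)
    missing = [l for l in labels if l not in profile]
    if missing:
        raise KeyError(f"profile missing leaves: {missing}")
    return {l: int(profile[l]) for l in labels}


def _wagner_edge_expectations(tree: dendropy.Tree, profile: Mapping[str, int]):
    """Expected 0<->1 transitions per edge, averaged over all MPRs.

    Unit-cost symmetric Wagner parsimony with a free root state.  Returns
    a dict edge-id -> expected transitions for one unit, plus the
    parsimony score.  Exact inside-outside dynamic programming with MPR
    counting (integer counts).
    """
    nodes = list(tree.postorder_node_iter())
    down: dict[int, list[float]] = {}
    cnt: dict[int, list[int]] = {}
    best: dict[int, list[float]] = {}      # per child, min over child state given parent state
    cntbest: dict[int, list[int]] = {}
    for nd in nodes:
        if nd.is_leaf():
            s = profile[nd.taxon.label]
            down[id(nd)] = [0.0 if s == 0 else _INF, 0.0 if s == 1 else _INF]
            cnt[id(nd)] = [1 if s == 0 else 0, 1 if s == 1 else 0]
        else:
            cost = [0.0, 0.0]
            count = [1, 1]
            for ch in nd.child_nodes():
                b = [0.0, 0.0]
                cb = [0, 0]
                for s in (0, 1):
                    opts = [down[id(ch)][t] + (0 if s == t else 1) for t in (0, 1)]
                    mn = min(opts)
                    b[s] = mn
                    cb[s] = sum(
                        cnt[id(ch)][t]
                        for t in (0, 1)
                        if opts[t] == mn and cnt[id(ch)][t] > 0
                    )
                best[id(ch)] = b
                cntbest[id(ch)] = cb
                for s in (0, 1):
                    cost[s] += b[s]
                    count[s] *= cb[s]
            down[id(nd)] = cost
            cnt[id(nd)] = count

    root = tree.seed_node
    score = min(down[id(root)])
    n_total = sum(
        cnt[id(root)][s] for s in (0, 1) if down[id(root)][s] == score
    )

    # outside costs/counts
    out: dict[int, list[float]] = {id(root): [0.0, 0.0]}
    cnt_out: dict[int, list[int]] = {id(root): [1, 1]}
    expect: dict[int, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() and nd is not root:
            pass
        children = nd.child_nodes()
        if not children:
            continue
        tot_best = [sum(best[id(ch)][s] for ch in children) for s in (0, 1)]
        for ch in children:
            # siblings-excluded aggregates, per parent state
            sib_cost = [tot_best[s] - best[id(ch)][s] for s in (0, 1)]
            sib_cnt = [1, 1]
            for s in (0, 1):
                p = 1
                for w in children:
                    if w is not ch:
                        p *= cntbest[id(w)][s]
                sib_cnt[s] = p
            o = [_INF, _INF]
            co = [0, 0]
            marg = 0
            for t in (0, 1):
                for s in (0, 1):
                    val = out[id(nd)][s] + sib_cost[s] + (0 if s == t else 1)
                    if val < o[t]:
                        o[t] = val
                        co[t] = 0
                    if val == o[t]:
                        co[t] += cnt_out[id(nd)][s] * sib_cnt[s]
            out[id(ch)] = o
            cnt_out[id(ch)] = co
            # edge marginal: joint (s, t) assignments achieving the optimum
            for s in (0, 1):
                for t in (0, 1):
                    if s == t:
                        continue
                    total = (
                        out[id(nd)][s]
                        + sib_cost[s]
                        + 1
                        + down[id(ch)][t]
                    )
                    if total == score:
                        marg += cnt_out[id(nd)][s] * sib_cnt[s] * cnt[id(ch)][t]
            expect[id(ch.edge)] = marg / n_total
    return expect, score


def parsimony_branch_lengths(
    topology: dendropy.Tree, m: OccurrenceMatrix
) -> dendropy.Tree:
    """Wagner-parsimony branch lengths on a fixed topology.

    Each branch length is the number of presence/absence state transitions
    on that branch, averaged uniformly over all most-parsimonious
    reconstructions and summed over units.  The topology is modified in
    place and returned.
    """
    tree = topology
    label_internal_nodes(tree)
    labels = set(leaf_labels(tree))
    if labels != set(m.genome_ids):
        raise ValueError("topology leaves must match occurrence-matrix genomes")
    totals: dict[int, float] = {
        id(nd.edge): 0.0
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None
    }
    for unit in m.unit_ids:
        profile = m.profile(unit)
        if sum(profile.values()) == 0:
            continue  # unit absent everywhere contributes nothing
        expect, _score = _wagner_edge_expectations(tree, profile)
        for eid, val in expect.items():
            totals[eid] += val
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = totals[id(nd.edge)]
    return tree


# ---------------------------------------------------------------------------
# rooting and height normalization


def _components_at_node(node: dendropy.Node) -> list[set[str]]:
    """Leaf sets of the components obtained by deleting ``node``."""
    comps = []
    neighbors = list(node.child_nodes())
    if node.parent_node is not None:
        neighbors.append(node.parent_node)
    for nb in neighbors:
        comp: set[str] = set()
        stack = [(nb, node)]
        while stack:
            cur, prev = stack.pop()
            if cur.is_leaf():
                comp.add(cur.taxon.label)
            nxt = list(cur.child_nodes())
            if cur.parent_node is not None:
                nxt.append(cur.parent_node)
            for other in nxt:
                if other is not prev:
                    stack.append((other, cur))
        comps.append(comp)
    return comps


def root_tree(
    t: dendropy.Tree,
    mode: str = "trifurcation",
    outgroup_id: str | None = None,
    superkingdoms: Mapping[str, str] | None = None,
) -> dendropy.Tree:
    """Root an unrooted tree at the superkingdom trifurcation or an outgroup.

    ``trifurcation`` mode finds the node whose removal separates the
    Archaea, Bacteria and Eukarya leaf sets (each must be monophyletic)
    and makes it the root, so the root has exactly three children.
    ``outgroup`` mode roots on the midpoint of the outgroup's pendant
    edge.  The tree is modified in place and returned.
    """
    if mode == "outgroup":
        if outgroup_id is None:
            raise ValueError("outgroup mode requires outgroup_id")
        leaf = None
        for lf in t.leaf_node_iter():
            if lf.taxon.label == outgroup_id:
                leaf = lf
                break
        if leaf is None:
            raise KeyError(f"outgroup {outgroup_id!r} not among leaves")
        ln = leaf.edge.length or 0.0
        t.reroot_at_edge(leaf.edge, length1=ln / 2.0, length2=ln / 2.0)
        t.is_rooted = True
        label_internal_nodes(t)
        return t
    if mode != "trifurcation":
        raise ValueError("mode must be 'trifurcation' or 'outgroup'")
    if superkingdoms is None:
        raise ValueError("trifurcation mode requires a leaf -> superkingdom map")
    groups: dict[str, set[str]] = {}
    for lf in t.leaf_node_iter():
        lab = lf.taxon.label
        if lab not in superkingdoms:
            raise KeyError(f"no superkingdom for leaf {lab!r}")
        groups.setdefault(superkingdoms[lab], set()).add(lab)
    if len(groups) != 3:
        raise ValueError(
            f"expected 3 superkingdoms among leaves, found {sorted(groups)}"
        )
    target = {frozenset(g) for g in groups.values()}
    for nd in t.preorder_node_iter():
        comps = _components_at_node(nd)
        if len(comps) == 3 and {frozenset(c) for c in comps} == target:
            t.reroot_at_node(nd, suppress_unifurcations=True)
            t.is_rooted = True
            label_internal_nodes(t)
            return t
    # diagnose: which superkingdoms are not clean splits
    t.encode_bipartitions()
    full = t.taxon_namespace.all_taxa_bitmask()
    masks = {
        min(b.split_bitmask & full, (~b.split_bitmask) & full)
        for b in t.bipartition_encoding
    }
    offenders = []
    for sk, leaves in groups.items():
        gmask = 0
        for tx in t.taxon_namespace:
            if tx.label in leaves:
                gmask |= t.taxon_namespace.taxon_bitmask(tx)
        if min(gmask, (~gmask) & full) not in masks:
            offenders.extend(sorted(leaves))
    raise ValueError(
        "superkingdoms are not monophyletic; offending leaves: "
        + ", ".join(offenders)
    )


def normalize_heights(t: dendropy.Tree) -> dendropy.Tree:
    """Assign every node a relative age in [0, 1].

    The age of a node is its maximum path length to any descendant leaf
    divided by the maximum root-to-leaf path length, so leaves have age 0
    exactly and the root age 1 exactly.  Ages are invariant to uniform
    rescaling of branch lengths and non-increasing from root to leaf.
    Stored on ``node.age``; the tree is modified in place and returned.
    """
    if t.seed_node is None:
        raise ValueError("empty tree")
    heights: dict[int, float] = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            heights[id(nd)] = 0.0
        else:
            heights[id(nd)] = max(
                heights[id(ch)] + (ch.edge.length or 0.0)
                for ch in nd.child_nodes()
            )
    total = heights[id(t.seed_node)]
    if total <= 0.0:
        logger.warning("all branch lengths zero; internal node ages set to 1")
        for nd in t.preorder_node_iter():
            nd.age = 0.0 if nd.is_leaf() else 1.0
        return t
    for nd in t.preorder_node_iter():
        nd.age = heights[id(nd)] / total
    t.seed_node.age = 1.0
    return t
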