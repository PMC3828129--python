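"""Parsimony-based age estimation for structural units.

Given a rooted species tree with normalized node ages (1 at the root, 0
at the leaves) and the presence/absence profile of a unit over the
leaves, these routines reconstruct a minimum-cost scenario of gain and
loss events and date the unit by the age of the earliest gain.

Three models are provided:

* **maximum parsimony** -- minimise S = L + g*G where L and G are the
  numbers of losses and gains and g is the gain weight (default 1, an
  equal penalty for both event types);
* **Dollo parsimony** -- exactly one gain, placed at the most recent
  common ancestor of all present leaves, plus the minimal set of losses;
* **fusion parsimony** -- maximum parsimony constrained to at most one
  gain inside the Eukaryotic subtree (lateral transfer being rare among
  Eukaryotes), unconstrained elsewhere.

The lineage above the root is taken to be absent, so presence at the
root itself costs one gain; "age 1" therefore means "gained at the
root".  Among co-optimal scenarios the one maximizing the earliest-gain
age is returned by default (``prefer_old=False`` minimizes it instead),
so the sensitivity of ages to this tie-break is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from foldspace.trees import node_id

_INF = float("inf")


@dataclass
class AgeScenario:
    """A gain/loss event set explaining a leaf profile on a tree."""

    gains: frozenset[str]
    losses: frozenset[str]
    gain_weight: float
    states: dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def cost(self) -> float:
        return len(self.losses) + self.gain_weight * len(self.gains)


@dataclass(frozen=True)
class AgeEstimate:
    unit_id: str
    model: str
    gain_weight: float
    age: float
    earliest_gain_node: str
    tree_id: str = ""


@dataclass(frozen=True)
class AgeGroupLabel:
    unit_id: str
    group: str
    cutoff: float


# ---------------------------------------------------------------------------
# scenario dynamic programming


def _check_profile(t: dendropy.Tree, profile: Mapping[str, int]) -> dict[str, int]:
    prof = {}
    for lf in t.leaf_node_iter():
        lab = lf.taxon.label
        if lab not in profile:
            raise KeyError(f"profile missing leaf {lab!r}")
        prof[lab] = int(profile[lab])
    if sum(prof.values()) == 0:
        raise ValueError("unit unobserved on every genome; age undefined")
    return prof


def _node_age(nd: dendropy.Node) -> float:
    age = getattr(nd, "age", None)
    if age is None:
        raise ValueError("tree has no normalized node ages; call normalize_heights")
    return float(age)


def _euk_clade_nodes(t: dendropy.Tree, euk_leaves: set[str]) -> set[int]:
    """Nodes of the subtree rooted at the MRCA of the Eukaryotic leaves."""
    if not euk_leaves:
        return set()
    mrca = _mrca(t, euk_leaves)
    return {id(nd) for nd in mrca.preorder_iter()}


def _mrca(t: dendropy.Tree, leaves: set[str]) -> dendropy.Node:
    paths = []
    want = set(leaves)
    for lf in t.leaf_node_iter():
        if lf.taxon.label in want:
            path = []
            nd = lf
            while nd is not None:
                path.append(nd)
                nd = nd.parent_node
            paths.append(list(reversed(path)))
    if not paths:
        raise ValueError("no matching leaves for MRCA")
    k = 0
    limit = min(len(p) for p in paths)
    while k < limit and all(p[k] is paths[0][k] for p in paths):
        k += 1
    return paths[0][k - 1]


def _scenario_dp(
    t: dendropy.Tree,
    profile: Mapping[str, int],
    g: float,
    euk_nodes: set[int] | None = None,
    euk_cap: int = 1,
    prefer_old: bool = True,
) -> AgeScenario:
    """Minimum-cost gain/loss scenario by Sankoff-style DP.

    State per node: (presence, eukaryotic gains used in the subtree).
    Costs: gain g on an absent->present edge, loss 1 on present->absent.
    Tie-break on the achievable earliest-gain age, lexicographically
    after cost (maximized when ``prefer_old``).
    """
    prof = _check_profile(t, profile)
    # The earliest-gain age of a scenario is the max of its gain-node
    # ages.  Encode a gain at age a as -a (prefer_old) so that the max
    # becomes a min and "smaller tie is better" holds lexicographically
    # after cost; for prefer_young keep +a and combine with max.
    if prefer_old:
        signed_age = lambda a: -a
        combine = min
        sentinel = 2.0
    else:
        signed_age = lambda a: a
        combine = max
        sentinel = -2.0

    # per node: dict (p, k) -> (cost, tie_key, decisions)
    # decisions: list of (child, (t, k')) used for backtracking
    tables: dict[int, dict] = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            s = prof[nd.taxon.label]
            tables[id(nd)] = {(s, 0): (0.0, sentinel, [])}
            continue
        # options per child, given the parent's presence state
        child_opts: list[dict] = []
        children = nd.child_nodes()
        for ch in children:
            opts: dict[int, dict[int, tuple]] = {0: {}, 1: {}}
            for (tc, kc), (ccost, ctie, _dec) in tables[id(ch)].items():
                for p in (0, 1):
                    if p == 0 and tc == 1:
                        edge_cost = g
                        gain_here = True
                    elif p == 1 and tc == 0:
                        edge_cost = 1.0
                        gain_here = False
                    else:
                        edge_cost = 0.0
                        gain_here = False
                    k_used = kc + (
                        1 if gain_here and euk_nodes and id(ch) in euk_nodes else 0
                    )
                    if euk_nodes and k_used > euk_cap:
                        continue
                    tie = ctie
                    if gain_here:
                        tie = combine(tie, signed_age(_node_age(ch)))
                    key = (ccost + edge_cost, tie)
                    cur = opts[p].get(k_used)
                    if cur is None or key < (cur[0], cur[1]):
                        opts[p][k_used] = (key[0], key[1], (tc, kc))
            child_opts.append(opts)
        table: dict = {}
        for p in (0, 1):
            # knapsack over children on eukaryotic gains used
            acc: dict[int, tuple] = {0: (0.0, sentinel, [])}
            feasible = True
            for ch, opts in zip(children, child_opts):
                nxt: dict[int, tuple] = {}
                for k0, (c0, t0, d0) in acc.items():
                    for kc, (cc, tc, choice) in opts[p].items():
                        k = k0 + kc
                        if euk_nodes and k > euk_cap:
                            continue
                        key = (c0 + cc, combine(t0, tc))
                        cur = nxt.get(k)
                        if cur is None or key < (cur[0], cur[1]):
                            nxt[k] = (key[0], key[1], d0 + [(ch, choice)])
                acc = nxt
                if not acc:
                    feasible = False
                    break
            if not feasible:
                continue
            for k, (c, tie, dec) in acc.items():
                table[(p, k)] = (c, tie, dec)
        tables[id(nd)] = table

    root = t.seed_node
    best = None
    for (p, k), (c, tie, _dec) in tables[id(root)].items():
        total = c + (g if p == 1 else 0.0)
        tie_f = tie
        if p == 1:
            tie_f = combine(tie_f, signed_age(_node_age(root)))
        key = (total, tie_f)
        if best is None or key < best[0]:
            best = (key, (p, k))
    assert best is not None
    root_state = best[1]

    # backtrack
    states: dict[str, int] = {}
    gains: set[str] = set()
    losses: set[str] = set()
    stack = [(root, root_state)]
    if root_state[0] == 1:
        gains.add(node_id(root))
    while stack:
        nd, (p, k) = stack.pop()
        states[node_id(nd)] = p
        if nd.is_leaf():
            continue
        _c, _tie, dec = tables[id(nd)][(p, k)]
        for ch, (tc, kc) in dec:
            if p == 0 and tc == 1:
                gains.add(node_id(ch))
            elif p == 1 and tc == 0:
                losses.add(node_id(ch))
            stack.append((ch, (tc, kc)))
    return AgeScenario(
        gains=frozenset(gains),
        losses=frozenset(losses),
        gain_weight=g,
        states=states,
    )


def mp_scenario(
    t: dendropy.Tree,
    profile: Mapping[str, int],
    g: float = 1.0,
    prefer_old: bool = True,
) -> AgeScenario:
    """Minimum-cost maximum-parsimony scenario (S = L + g*G)."""
    if g <= 0:
        raise ValueError("gain weight must be positive")
    return _scenario_dp(t, profile, g, euk_nodes=None, prefer_old=prefer_old)


def fusion_scenario(
    t: dendropy.Tree,
    profile: Mapping[str, int],
    g: float = 1.0,
    euk_leaves: Iterable[str] | None = None,
    prefer_old: bool = True,
) -> AgeScenario:
    """Maximum parsimony with at most one gain in the Eukaryotic subtree."""
    if g <= 0:
        raise ValueError("gain weight must be positive")
    if euk_leaves is None:
        raise ValueError("fusion parsimony needs the Eukaryotic leaf set")
    euk = set(euk_leaves)
    leaf_set = {lf.taxon.label for lf in t.leaf_node_iter()}
    unknown = euk - leaf_set
    if unknown:
        raise KeyError(f"eukaryotic leaves not on tree: {sorted(unknown)}")
    euk_nodes = _euk_clade_nodes(t, euk)
    return _scenario_dp(
        t, profile, g, euk_nodes=euk_nodes, euk_cap=1, prefer_old=prefer_old
    )


def dollo_age(
    t: dendropy.Tree, profile: Mapping[str, int], unit_id: str = "", tree_id: str = ""
) -> AgeEstimate:
    """Dollo-parsimony age: single gain at the MRCA of the present leaves."""
    scenario = dollo_scenario(t, profile)
    (gain,) = scenario.gains
    nodes = {node_id(nd): nd for nd in t.preorder_node_iter()}
    return AgeEstimate(
        unit_id=unit_id,
        model="dollo",
        gain_weight=float("nan"),
        age=_node_age(nodes[gain]),
        earliest_gain_node=gain,
        tree_id=tree_id,
    )


def dollo_scenario(t: dendropy.Tree, profile: Mapping[str, int]) -> AgeScenario:
    """Single gain at the presence MRCA plus minimal losses below it.

    Losses are the maximal all-absent subtrees inside the gain clade.
    """
    prof = _check_profile(t, profile)
    present = {lab for lab, v in prof.items() if v == 1}
    mrca = _mrca(t, present)
    all_absent: dict[int, bool] = {}
    for nd in mrca.postorder_iter():
        if nd.is_leaf():
            all_absent[id(nd)] = prof[nd.taxon.label] == 0
        else:
            all_absent[id(nd)] = all(
                all_absent[id(ch)] for ch in nd.child_nodes()
            )
    losses: set[str] = set()
    states: dict[str, int] = {}
    stack = [(mrca, True)]
    while stack:
        nd, inherited = stack.pop()
        if inherited and all_absent[id(nd)]:
            losses.add(node_id(nd))
            inherited = False
        states[node_id(nd)] = 1 if inherited else 0
        for ch in nd.child_nodes():
            stack.append((ch, inherited))
    # nodes outside the MRCA clade are absent
    for nd in t.preorder_node_iter():
        states.setdefault(node_id(nd), 0)
    return AgeScenario(
        gains=frozenset({node_id(mrca)}),
        losses=frozenset(losses),
        gain_weight=1.0,
        states=states,
    )


def age_from_scenario(s: AgeScenario, t: dendropy.Tree) -> float:
    """Age of the earliest (oldest) gain node in a scenario."""
    if not s.gains:
        raise ValueError("scenario has no gain events")
    nodes = {node_id(nd): nd for nd in t.preorder_node_iter()}
    return max(_node_age(nodes[gid]) for gid in s.gains)


def estimate_age(
    t: dendropy.Tree,
    profile: Mapping[str, int],
    model: str = "mp",
    g: float = 1.0,
    euk_leaves: Iterable[str] | None = None,
    prefer_old: bool = True,
    unit_id: str = "",
    tree_id: str = "",
) -> AgeEstimate:
    """Estimate the age of one unit under the chosen parsimony model."""
    if model == "dollo":
        est = dollo_age(t, profile, unit_id=unit_id, tree_id=tree_id)
        return est
    if model == "mp":
        scen = mp_scenario(t, profile, g=g, prefer_old=prefer_old)
    elif model == "fusion":
        scen = fusion_scenario(
            t, profile, g=g, euk_leaves=euk_leaves, prefer_old=prefer_old
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    nodes = {node_id(nd): nd for nd in t.preorder_node_iter()}
    ages = {gid: _node_age(nodes[gid]) for gid in scen.gains}
    earliest = max(ages, key=lambda gid: ages[gid])
    return AgeEstimate(
        unit_id=unit_id,
        model=model,
        gain_weight=g,
        age=ages[earliest],
        earliest_gain_node=earliest,
        tree_id=tree_id,
    )


# ---------------------------------------------------------------------------
# age groups


def assign_age_groups(
    ages: Sequence[AgeEstimate] | Mapping[str, float],
    cutoff: float = 0.1,
    ancient_tol: float = 1e-9,
) -> list[AgeGroupLabel]:
    """Label units as ancient (age = 1), new-born (age <= cutoff) or middle."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    if isinstance(ages, Mapping):
        items = list(ages.items())
    else:
        items = [(a.unit_id, a.age) for a in ages]
    labels = []
    for uid, age in items:
        if age >= 1.0 - ancient_tol:
            group = "ancient"
        elif age <= cutoff:
            group = "newborn"
        else:
            group = "middle"
        labels.append(AgeGroupLabel(unit_id=uid, group=group, cutoff=cutoff))
    return labels


def auto_cutoff(ages: Mapping[str, float], ancient_tol: float = 1e-9) -> float:
    """Cut-off equalizing new-born and ancient group sizes as nearly as possible.

    Candidate cut-offs are the distinct non-ancient age values; the one
    minimizing | |newborn| - |ancient| | (smallest such cut-off on ties)
    is returned.
    """
    vals = sorted(ages.values())
    n_ancient = sum(1 for v in vals if v >= 1.0 - ancient_tol)
    candidates = sorted({v for v in vals if 0.0 < v < 1.0 - ancient_tol})
    candidates = [0.5 * candidates[0]] + candidates if candidates else [0.5]
    best_c, best_gap = candidates[0], float("inf")
    for c in candidates:
        n_new = sum(1 for v in vals if v <= c)
        gap = abs(n_new - n_ancient)
        if gap < best_gap:
            best_c, best_gap = c, gap
    return best_c


def gain_weight_sweep(
    t: dendropy.Tree,
    profiles: Mapping[str, Mapping[str, int]],
    g_values: Sequence[float] = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0),
    prefer_old: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ages per unit for a range of gain weights, plus their rank agreement.

    Returns ``(ages, rho)``: a units x g table of maximum-parsimony ages
    and the Spearman correlation matrix between the g columns.
    """
    if any(g <= 0 for g in g_values):
        raise ValueError("gain weights must be positive")
    table = {}
    for g in g_values:
        table[g] = {
            uid: estimate_age(
                t, prof, model="mp", g=g, prefer_old=prefer_old, unit_id=uid
            ).age
            for uid, prof in profiles.items()
        }
    ages = pd.DataFrame(table)
    ages.index.name = "unit_id"
    k = len(g_values)
    rho = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = ages.iloc[:, i], ages.iloc[:, j]
            if a.nunique() < 2 or b.nunique() < 2:
                # constant age vector: rank correlation undefined
                r = float("nan") if not a.equals(b) else 1.0
            else:
                r = spearmanr(a, b).statistic
            rho[i, j] = rho[j, i] = r
    rho_df = pd.DataFrame(rho, index=list(g_values), columns=list(g_values))
    return ages, rho_df
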