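"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here at desk scale:
species trees with three superkingdom clades under a trifurcating root,
binary occurrence profiles evolved by a birth-node + branch-loss +
lateral-transfer + annotation-noise process (so the true birth node and
age of every unit are known), genome metadata tables with removal
flags, toy domain structures with plausible Calpha geometry and
annotations, beta-sheet topologies, and functional term annotations
with planted enrichment.

Default simulation conditions: 12 genomes (4 per superkingdom), 500
units, per-branch loss rate 0.1, lateral-transfer rate 0.01 and 1%
false-positive/false-negative annotation noise per leaf.  Loss is
absorbing: a lineage that loses a unit never regains it except through
an explicit lateral-transfer event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from foldspace.descriptors import DomainStructure, ResidueAnnotation
from foldspace.motifs import SheetTopology, Strand
from foldspace.occurrence import GenomeRecord, OccurrenceMatrix
from foldspace.trees import label_internal_nodes, node_id, normalize_heights

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_SK_PREFIX = {"Archaea": "A", "Bacteria": "B", "Eukarya": "E"}


@dataclass
class SimulationConfig:
    """Conditions for the profile-evolution simulation."""

    n_leaves: dict = field(
        default_factory=lambda: {"Archaea": 4, "Bacteria": 4, "Eukarya": 4}
    )
    birth_node_distribution: str = "uniform_nodes"
    loss_rate: float = 0.1
    hgt_rate: float = 0.01
    fp_rate: float = 0.01
    fn_rate: float = 0.01
    n_units: int = 500
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("loss_rate", "hgt_rate", "fp_rate", "fn_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.birth_node_distribution not in (
            "uniform_nodes",
            "branch_length_weighted",
        ):
            raise ValueError(
                f"unknown birth distribution {self.birth_node_distribution!r}"
            )


@dataclass(frozen=True)
class UnitTruth:
    birth_node: str
    true_age: float
    loss_branches: frozenset[str]
    hgt_branches: frozenset[str]
    flipped_leaves: frozenset[str]


@dataclass
class SimulationTruth:
    units: dict[str, UnitTruth]
    n_redraws: int = 0


# ---------------------------------------------------------------------------
# trees


def random_tree(
    n_leaves: dict | None = None, seed: int = 1
) -> dendropy.Tree:
    """Random rooted species tree with a superkingdom trifurcation.

    Each superkingdom clade is grown by random sequential joining with
    exponential(1) branch lengths; the three clade roots hang off a
    trifurcating root.  Node heights are normalized so leaves have age 0
    and the root age 1; leaf labels are prefixed by superkingdom
    (``A``/``B``/``E``) and each leaf carries a ``superkingdom``
    attribute.
    """
    if n_leaves is None:
        n_leaves = {"Archaea": 4, "Bacteria": 4, "Eukarya": 4}
    if sum(n_leaves.values()) < 4:
        raise ValueError("need at least 4 leaves in total")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    for sk in ("Archaea", "Bacteria", "Eukarya"):
        count = n_leaves.get(sk, 0)
        if count < 1:
            raise ValueError(f"every superkingdom needs >= 1 leaf ({sk})")
        nodes = []
        for i in range(count):
            label = f"{_SK_PREFIX[sk]}{i + 1:02d}"
            taxon = tns.new_taxon(label)
            nd = dendropy.Node(taxon=taxon)
            nd.superkingdom = sk
            nd.edge.length = float(rng.exponential(1.0))
            nodes.append(nd)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            joined = dendropy.Node()
            joined.add_child(nodes[i])
            joined.add_child(nodes[j])
            joined.edge.length = float(rng.exponential(1.0))
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
            nodes.append(joined)
        root.add_child(nodes[0])
    tree.is_rooted = True
    label_internal_nodes(tree)
    normalize_heights(tree)
    return tree


def superkingdom_map(tree: dendropy.Tree) -> dict[str, str]:
    """Leaf label -> superkingdom for trees built by :func:`random_tree`."""
    prefix_to_sk = {v: k for k, v in _SK_PREFIX.items()}
    out = {}
    for lf in tree.leaf_node_iter():
        sk = getattr(lf, "superkingdom", None)
        if sk is None:
            sk = prefix_to_sk.get(lf.taxon.label[0])
            if sk is None:
                raise ValueError(f"cannot infer superkingdom of {lf.taxon.label!r}")
        out[lf.taxon.label] = sk
    return out


# ---------------------------------------------------------------------------
# occurrence profiles


def _draw_birth_node(tree, rng, distribution: str):
    nodes = list(tree.preorder_node_iter())
    if distribution == "uniform_nodes":
        return nodes[rng.integers(len(nodes))]
    # branch_length_weighted: probability proportional to the parent-edge
    # length; the root, which has no parent edge, gets the mean edge length
    weights = []
    for nd in nodes:
        if nd.parent_node is None:
            weights.append(np.nan)
        else:
            weights.append(nd.edge.length or 0.0)
    w = np.asarray(weights, dtype=float)
    w[np.isnan(w)] = np.nanmean(w) if np.isfinite(np.nanmean(w)) else 1.0
    if w.sum() <= 0:
        w = np.ones_like(w)
    return nodes[rng.choice(len(nodes), p=w / w.sum())]


def simulate_profiles(
    tree: dendropy.Tree, config: SimulationConfig
) -> tuple[OccurrenceMatrix, SimulationTruth]:
    """Evolve binary unit profiles on a tree with known ground truth.

    Per unit: a birth node is drawn and presence descends from it; each
    branch below a present node loses the unit with ``loss_rate``
    (absorbing); each branch whose parent lacks the unit (excluding the
    birth node's ancestors) gains it laterally with ``hgt_rate``; leaf
    states are then flipped with ``fp_rate`` / ``fn_rate``.  Units that
    end up absent everywhere are re-drawn (counted in the truth record),
    since their age would be undefined.
    """
    rng = np.random.default_rng(config.seed)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    units: dict[str, dict[str, int]] = {}
    truth: dict[str, UnitTruth] = {}
    n_redraws = 0
    width = max(4, len(str(config.n_units)))
    made = 0
    while made < config.n_units:
        birth = _draw_birth_node(tree, rng, config.birth_node_distribution)
        ancestors = set()
        nd = birth.parent_node
        while nd is not None:
            ancestors.add(id(nd))
            nd = nd.parent_node
        present: dict[int, bool] = {}
        losses: set[str] = set()
        hgts: set[str] = set()
        for nd in tree.preorder_node_iter():
            if nd is birth:
                present[id(nd)] = True
            elif id(nd) in ancestors or nd.parent_node is None:
                present[id(nd)] = False
            elif present[id(nd.parent_node)]:
                if rng.random() < config.loss_rate:
                    present[id(nd)] = False
                    losses.add(node_id(nd))
                else:
                    present[id(nd)] = True
            else:
                if rng.random() < config.hgt_rate:
                    present[id(nd)] = True
                    hgts.add(node_id(nd))
                else:
                    present[id(nd)] = False
        profile = {}
        flipped: set[str] = set()
        for lf in tree.leaf_node_iter():
            state = 1 if present[id(lf)] else 0
            rate = config.fn_rate if state == 1 else config.fp_rate
            if rng.random() < rate:
                state = 1 - state
                flipped.add(lf.taxon.label)
            profile[lf.taxon.label] = state
        if sum(profile.values()) == 0:
            n_redraws += 1
            continue
        uid = f"U{made + 1:0{width}d}"
        units[uid] = profile
        truth[uid] = UnitTruth(
            birth_node=node_id(birth),
            true_age=float(birth.age),
            loss_branches=frozenset(losses),
            hgt_branches=frozenset(hgts),
            flipped_leaves=frozenset(flipped),
        )
        made += 1
    df = pd.DataFrame(
        [[units[u][g] for g in leaves] for u in units],
        index=list(units),
        columns=leaves,
        dtype=np.int8,
    )
    return (
        OccurrenceMatrix(df=df, level="superfamily"),
        SimulationTruth(units=truth, n_redraws=n_redraws),
    )


def synthetic_fold_map(
    unit_ids, n_folds: int | None = None, seed: int = 1
) -> dict[str, str]:
    """Random superfamily -> fold assignment (every fold non-empty)."""
    unit_ids = list(unit_ids)
    if n_folds is None:
        n_folds = max(1, len(unit_ids) // 3)
    if not 1 <= n_folds <= len(unit_ids):
        raise ValueError("n_folds must lie in [1, number of units]")
    rng = np.random.default_rng(seed)
    folds = [f"F{k + 1:04d}" for k in range(n_folds)]
    assignment = {u: folds[k % n_folds] for k, u in enumerate(unit_ids)}
    perm = rng.permutation(len(unit_ids))
    return {unit_ids[i]: assignment[unit_ids[int(j)]] for i, j in enumerate(perm)}


# ---------------------------------------------------------------------------
# genome metadata


def synthetic_genome_table(
    n_total: int = 1496,
    n_pathogen: int = 407,
    n_candidatus: int = 31,
    n_manual: int = 44,
    seed: int = 1,
) -> list[GenomeRecord]:
    """Genome metadata table with disjoint removal-flag categories.

    Defaults reproduce the composition of the genome set the age
    analysis was designed around: 1,496 genomes of which 407 pathogens,
    31 *candidatus* taxa and 44 manual removals, leaving 1,014.
    """
    if n_pathogen + n_candidatus + n_manual > n_total:
        raise ValueError("flagged categories exceed the table size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_total)
    pathogen = set(order[:n_pathogen])
    candidatus = set(order[n_pathogen : n_pathogen + n_candidatus])
    manual = set(order[n_pathogen + n_candidatus : n_pathogen + n_candidatus + n_manual])
    sks = rng.choice(
        ["Bacteria", "Eukarya", "Archaea"], size=n_total, p=[0.65, 0.25, 0.10]
    )
    records = []
    for i in range(n_total):
        sk = str(sks[i])
        records.append(
            GenomeRecord(
                genome_id=f"G{i + 1:04d}",
                superkingdom=sk,
                multicellular=bool(sk == "Eukarya" and rng.random() < 0.8),
                pathogen=i in pathogen,
                candidatus=i in candidatus,
                manual_remove=i in manual,
            )
        )
    return records


# ---------------------------------------------------------------------------
# toy domain structures


def _helix_segment(n: int) -> np.ndarray:
    # ideal alpha-helix Calpha spiral: radius 2.3 A, rise 1.5 A,
    # 100 degrees per residue -> consecutive Calpha spacing ~3.8 A
    k = np.arange(n)
    theta = np.deg2rad(100.0) * k
    return np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * k]
    )


def _strand_segment(n: int) -> np.ndarray:
    # near-extended zigzag: 3.3 A along the axis, alternating 0.95 A sway
    k = np.arange(n)
    return np.column_stack(
        [3.3 * k, 0.95 * (-1.0) ** k, np.zeros(n)]
    )


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def synthetic_domain(
    plan: list[tuple[str, int]],
    seed: int = 1,
    domain_id: str = "D0001",
    superfamily_id: str = "SF0001",
    target_buried_fraction: float = 0.35,
    disulphide_pairs: int = 0,
    topology: SheetTopology | None = None,
    max_retries: int = 200,
) -> DomainStructure:
    """Build a toy domain with plausible Calpha geometry and annotations.

    ``plan`` lists (ss_element, length) segments in chain order.
    Helices are ideal spirals, strands near-extended zigzags, coils
    seeded random walks; segments are joined by 3.8 A virtual bonds with
    clash avoidance (no two non-consecutive Calphas closer than 3.5 A).
    Relative exposures are sampled so the buried fraction (exposure
    below 7%) matches ``target_buried_fraction``, biased toward residues
    near the centroid.  ``disulphide_pairs`` spatially close residue
    pairs are converted to cysteine bridges.  If the plan contains >= 2
    strands and no explicit ``topology``, an antiparallel meander
    topology is recorded.
    """
    total = sum(n for _ss, n in plan)
    if total < 10:
        raise ValueError("domain must have at least 10 residues")
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    ss: list[str] = []
    strand_ids: list[str | None] = []
    n_strands = 0

    def clashes(pts: np.ndarray, existing: np.ndarray) -> bool:
        if len(existing) == 0:
            return False
        d = np.linalg.norm(pts[:, None, :] - existing[None, :, :], axis=-1)
        # the joint between the last existing point and the first new one
        # is a consecutive pair and may come as close as a virtual bond
        d[0, -1] = np.inf
        return bool((d < 3.5).any())

    for seg_idx, (element, n) in enumerate(plan):
        if element not in ("helix", "strand", "coil"):
            raise ValueError(f"unknown ss element {element!r}")
        placed = None
        for _attempt in range(max_retries):
            if element == "coil":
                # seeded random walk with 3.8 A steps
                start = (
                    coords[-1] if coords else np.zeros(3)
                )
                pts = [np.asarray(start, dtype=float)]
                for _ in range(n):
                    step = rng.normal(size=3)
                    step *= 3.8 / np.linalg.norm(step)
                    pts.append(pts[-1] + step)
                seg = np.array(pts[1:])
            else:
                local = _helix_segment(n) if element == "helix" else _strand_segment(n)
                local = local @ _random_rotation(rng).T
                if coords:
                    direction = rng.normal(size=3)
                    # bias the chain back toward the centroid for compactness
                    existing = np.array(coords)
                    direction = 0.6 * direction + 0.4 * (
                        existing.mean(axis=0) - coords[-1]
                    ) / max(np.linalg.norm(existing.mean(axis=0) - coords[-1]), 1e-9)
                    direction *= 3.8 / np.linalg.norm(direction)
                    seg = local - local[0] + coords[-1] + direction
                else:
                    seg = local - local[0]
            existing = np.array(coords) if coords else np.empty((0, 3))
            if not clashes(seg, existing):
                placed = seg
                break
        if placed is None:
            raise RuntimeError(
                f"could not place segment {seg_idx} without clashes "
                f"after {max_retries} retries"
            )
        sid = None
        if element == "strand":
            n_strands += 1
            sid = f"S{n_strands}"
        coords.extend(list(placed))
        ss.extend([element] * n)
        strand_ids.extend([sid] * n)

    coords_arr = np.array(coords)
    sequence = list(rng.choice(list(AMINO_ACIDS), size=total))

    # exposure: buried residues biased toward the centroid
    centroid = coords_arr.mean(axis=0)
    dist = np.linalg.norm(coords_arr - centroid, axis=1)
    n_buried = int(round(target_buried_fraction * total))
    buried_idx = set(np.argsort(dist)[:n_buried].tolist())
    exposure = np.where(
        np.isin(np.arange(total), list(buried_idx)),
        rng.uniform(0.0, 6.99, size=total),
        rng.uniform(7.01, 100.0, size=total),
    )

    partners: dict[int, int] = {}
    if disulphide_pairs > 0:
        candidates = sorted(range(total), key=lambda i: dist[i])
        free = [i for i in candidates]
        pairs_made = 0
        while pairs_made < disulphide_pairs and len(free) >= 2:
            i = free.pop(0)
            # closest spatial neighbour at least 3 residues away in sequence
            best = None
            for j in free:
                if abs(j - i) < 3:
                    continue
                dij = np.linalg.norm(coords_arr[i] - coords_arr[j])
                if best is None or dij < best[1]:
                    best = (j, dij)
            if best is None:
                break
            j = best[0]
            free.remove(j)
            partners[i] = j
            partners[j] = i
            sequence[i] = "C"
            sequence[j] = "C"
            pairs_made += 1

    annotations = [
        ResidueAnnotation(
            ss_element=ss[i],
            strand_id=strand_ids[i],
            relative_exposure=float(exposure[i]),
            disulphide_partner=partners.get(i),
        )
        for i in range(total)
    ]
    if topology is None and n_strands >= 2:
        topology = meander_topology(n_strands, sheet_id=f"{domain_id}_sheet")
    return DomainStructure(
        domain_id=domain_id,
        superfamily_id=superfamily_id,
        sequence="".join(sequence),
        ca_coords=coords_arr,
        annotations=annotations,
        sheet_topology=topology,
    )


# ---------------------------------------------------------------------------
# canned sheet topologies


def meander_topology(n_strands: int, sheet_id: str = "sheet") -> SheetTopology:
    """Simple up-down antiparallel meander of ``n_strands`` strands."""
    strands = [
        Strand(strand_id=f"S{i + 1}", sequence_order=i + 1, spatial_position=i + 1)
        for i in range(n_strands)
    ]
    pairings = [
        (f"S{i + 1}", f"S{i + 2}", "antiparallel") for i in range(n_strands - 1)
    ]
    return SheetTopology(sheet_id=sheet_id, strands=strands, pairings=pairings)


def greek_key_topology(sheet_id: str = "greek_key") -> SheetTopology:
    """Four antiparallel strands with spatial order (+3, -1, -1)."""
    positions = {1: 1, 2: 4, 3: 3, 4: 2}
    strands = [
        Strand(strand_id=f"S{i}", sequence_order=i, spatial_position=positions[i])
        for i in range(1, 5)
    ]
    by_pos = sorted(strands, key=lambda s: s.spatial_position)
    pairings = [
        (a.strand_id, b.strand_id, "antiparallel")
        for a, b in zip(by_pos, by_pos[1:])
    ]
    return SheetTopology(sheet_id=sheet_id, strands=strands, pairings=pairings)


def jelly_roll_topology(sheet_id: str = "jelly_roll") -> SheetTopology:
    """A greek key (strands 2-5) wrapped by outer strands 1 and 6."""
    positions = {1: 6, 2: 2, 3: 5, 4: 4, 5: 3, 6: 1}
    strands = [
        Strand(strand_id=f"S{i}", sequence_order=i, spatial_position=positions[i])
        for i in range(1, 7)
    ]
    by_pos = sorted(strands, key=lambda s: s.spatial_position)
    pairings = [
        (a.strand_id, b.strand_id, "antiparallel")
        for a, b in zip(by_pos, by_pos[1:])
    ]
    return SheetTopology(sheet_id=sheet_id, strands=strands, pairings=pairings)


# ---------------------------------------------------------------------------
# functional annotations


def synthetic_go(
    superfamilies,
    groups: dict[str, str],
    planted: list[tuple[str, str, float, float]],
    seed: int = 1,
) -> dict[str, set[str]]:
    """Bernoulli term annotations with planted group enrichment.

    ``planted`` rows are (term, group, rate_in, rate_out): the term
    annotates members of the group with probability ``rate_in`` and all
    other superfamilies with ``rate_out``.
    """
    rng = np.random.default_rng(seed)
    superfamilies = list(superfamilies)
    annotations: dict[str, set[str]] = {sf: set() for sf in superfamilies}
    for term, group, rate_in, rate_out in planted:
        if not (0.0 <= rate_in <= 1.0 and 0.0 <= rate_out <= 1.0):
            raise ValueError("annotation rates must lie in [0, 1]")
        for sf in superfamilies:
            rate = rate_in if groups.get(sf) == group else rate_out
            if rng.random() < rate:
                annotations[sf].add(term)
    return annotations


def write_go_tsv(annotations: dict[str, set[str]], path) -> None:
    rows = [
        {"superfamily_id": sf, "term_id": term}
        for sf in sorted(annotations)
        for term in sorted(annotations[sf])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_go_tsv(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.superfamily_id), set()).add(str(row.term_id))
    return out
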