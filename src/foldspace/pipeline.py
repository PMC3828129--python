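"""End-to-end analysis pipeline on synthetic data.

Runs the full study design at desk scale from one seeded configuration:
generate a genome table and filter it; evolve unit occurrence profiles
on a random three-superkingdom tree; build the eight tree
configurations (backbone topology with Wagner-parsimony branch lengths,
neighbour-joining jackknife consensus under Jaccard and Bray-Curtis
distances, and a provided topology with Wagner-parsimony branch
lengths, each at superfamily and fold level); estimate ages under
maximum, Dollo and fusion parsimony; label age groups; generate toy
domain structures whose properties covary with true age; compute
descriptor contrasts, motif sets, functional enrichment and the
structure-versus-function comparison; and collect everything into a
deterministic report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from foldspace import synth
from foldspace.ages import (
    assign_age_groups,
    auto_cutoff,
    estimate_age,
)
from foldspace.descriptors import (
    amino_acid_propensities,
    describe_domain,
    summarize_superfamily,
)
from foldspace.motifs import SheetTopology, Strand, classify_superfamily_motifs, detect_motifs
from foldspace.occurrence import (
    collapse_to_fold,
    distance_matrix,
    filter_genomes,
)
from foldspace.stats import (
    hypergeometric_enrichment,
    mann_whitney_ties,
    structure_vs_function_contrast,
)
from foldspace.trees import (
    fit_branch_lengths_ls,
    jackknife_samples,
    majority_rule_consensus,
    neighbor_joining,
    normalize_heights,
    parsimony_branch_lengths,
    read_newick,
    root_tree,
)

logger = logging.getLogger(__name__)

DEFAULT_TREE_METHODS = (
    "backbone-wagner",
    "nj-jaccard",
    "nj-braycurtis",
    "provided-wagner",
)
LEVELS = ("superfamily", "fold")


@dataclass
class PipelineConfig:
    """Single-seed configuration for a full synthetic run."""

    seed: int = 1
    n_leaves: dict = field(
        default_factory=lambda: {"Archaea": 4, "Bacteria": 4, "Eukarya": 4}
    )
    n_units: int = 500
    loss_rate: float = 0.1
    hgt_rate: float = 0.01
    fp_rate: float = 0.01
    fn_rate: float = 0.01
    n_folds: int | None = None
    tree_methods: tuple = DEFAULT_TREE_METHODS
    provided_topology: str | None = None  # newick; defaults to the true topology
    n_jackknife: int = 100
    gain_weight: float = 1.0
    cutoff: float | str = 0.1  # numeric or "auto"
    n_struct_superfamilies: int = 60
    n_go_terms_planted: int = 10
    alpha: float = 0.05

    def tree_recipes(self) -> list[tuple[str, str]]:
        return [(m, level) for m in self.tree_methods for level in LEVELS]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a configuration from a YAML file (unknown keys rejected)."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tree_methods" in data:
            data["tree_methods"] = tuple(data["tree_methods"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RunReport:
    params: dict
    counts: dict
    group_sizes: dict
    tree_warnings: list
    concordance_superfamily: dict
    model_agreement: dict
    descriptor_contrasts: dict
    propensities: dict
    enrichment: dict
    motifs: dict
    contrast: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# tree recipes


def _clone_topology(tree):
    clone = tree.clone(depth=1)
    return clone


def build_tree(method: str, level: str, matrices, true_tree, cfg: PipelineConfig):
    """Build one rooted, height-normalized tree for a recipe.

    Returns (tree, warning-or-None).
    """
    m = matrices[level]
    warning = None
    if method in ("backbone-wagner", "provided-wagner"):
        if method == "provided-wagner" and cfg.provided_topology is not None:
            topo = read_newick(cfg.provided_topology)
            topo.is_rooted = True
        else:
            topo = _clone_topology(true_tree)
        tree = parsimony_branch_lengths(topo, m)
    elif method in ("nj-jaccard", "nj-braycurtis"):
        metric = "jaccard" if method == "nj-jaccard" else "braycurtis"
        D = distance_matrix(m, metric=metric)
        offset = sum(ord(c) for c in f"{method}/{level}")  # deterministic
        samples = jackknife_samples(
            m, n_samples=cfg.n_jackknife, fraction=0.5,
            seed=(cfg.seed * 131 + offset) % (2**31),
        )
        ensemble = []
        tns = None
        for s in samples:
            ds = distance_matrix(s, metric=metric)
            t = neighbor_joining(ds)
            if tns is None:
                tns = t.taxon_namespace
            else:
                t = read_newick(t.as_string(schema="newick"))
                t.taxon_namespace.clear()
                t = _retaxon(t, tns)
            ensemble.append(t)
        consensus = majority_rule_consensus(ensemble, extended=True)
        sk = synth.superkingdom_map(true_tree)
        try:
            consensus = root_tree(consensus, mode="trifurcation", superkingdoms=sk)
        except ValueError:
            outgroup = sorted(
                lab for lab, s in sk.items() if s == "Archaea"
            )[0]
            warning = (
                f"{method}/{level}: superkingdoms not monophyletic in the "
                f"consensus; rooted on archaeal outgroup {outgroup}"
            )
            consensus = root_tree(consensus, mode="outgroup", outgroup_id=outgroup)
        tree = fit_branch_lengths_ls(consensus, D)
    else:
        raise ValueError(f"unknown tree method {method!r}")
    return normalize_heights(tree), warning


def _retaxon(tree, tns):
    """Re-bind a tree's leaves to a shared taxon namespace."""
    import dendropy

    return dendropy.Tree.get(
        data=tree.as_string(schema="newick"),
        schema="newick",
        taxon_namespace=tns,
        preserve_underscores=True,
    )


# ---------------------------------------------------------------------------
# concordance


def concordance(ages_by_recipe: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Pairwise Spearman correlations between age vectors on shared units."""
    names = list(ages_by_recipe)
    if len(names) < 2:
        raise ValueError("need at least two age vectors")
    shared = set.intersection(*(set(v) for v in ages_by_recipe.values()))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared units")
    shared = sorted(shared)
    mat = np.ones((len(names), len(names)))
    vecs = {n: np.array([ages_by_recipe[n][u] for u in shared]) for n in names}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rho = spearmanr(vecs[names[i]], vecs[names[j]]).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# structural stage helpers


def _parallel_meander(n_strands: int, sheet_id: str) -> SheetTopology:
    strands = [
        Strand(strand_id=f"S{i + 1}", sequence_order=i + 1, spatial_position=i + 1)
        for i in range(n_strands)
    ]
    pairings = [
        (f"S{i + 1}", f"S{i + 2}", "parallel") for i in range(n_strands - 1)
    ]
    return SheetTopology(sheet_id=sheet_id, strands=strands, pairings=pairings)


def _make_structures(chosen: list[tuple[str, float]], seed: int):
    """Toy domains whose properties covary with true age.

    Older superfamilies get longer domains, more buried cores and a
    higher chance of parallel sheets; younger ones more disulphides,
    greek keys and jelly rolls (antiparallel motifs skew young).
    Returns (domains_by_superfamily, strand label intent per sf).
    """
    rng = np.random.default_rng(seed)
    domains = {}
    for k, (sf, age) in enumerate(chosen):
        n_dom = 1 + int(rng.random() < 0.4)
        doms = []
        for d in range(n_dom):
            length = int(50 + 70 * age + rng.normal(0, 8))
            length = max(30, length)
            n_strands = 4 if rng.random() < 0.8 else 6
            strand_len = 5
            helix_len = max(6, (length - n_strands * strand_len) // 3)
            plan = []
            for s in range(n_strands):
                plan.append(("strand", strand_len))
                if s < n_strands - 1:
                    plan.append(("coil", 3))
            plan.append(("coil", 2))
            plan.append(("helix", helix_len))
            rest = length - sum(n for _e, n in plan)
            if rest > 0:
                plan.append(("coil", rest))
            parallel = rng.random() < (0.15 + 0.55 * age)
            sheet_id = f"{sf}_d{d}_sheet"
            if parallel:
                topo = _parallel_meander(n_strands, sheet_id)
            else:
                u = rng.random()
                motif_p = 0.45 * (1.0 - 0.5 * age)
                if n_strands >= 6 and u < motif_p:
                    topo = synth.jelly_roll_topology(sheet_id)
                elif n_strands == 4 and u < motif_p:
                    topo = synth.greek_key_topology(sheet_id)
                else:
                    topo = synth.meander_topology(n_strands, sheet_id)
            ds_pairs = int(rng.random() < max(0.05, 0.5 - 0.45 * age))
            dom = synth.synthetic_domain(
                plan,
                seed=int(rng.integers(2**31)),
                domain_id=f"{sf}_d{d}",
                superfamily_id=sf,
                target_buried_fraction=0.22 + 0.16 * age,
                disulphide_pairs=ds_pairs,
                topology=topo,
            )
            doms.append(dom)
        domains[sf] = doms
    return domains


def _mw_dict(res) -> dict:
    return {
        "U": res.U, "n1": res.n1, "n2": res.n2, "z": res.z,
        "p_two_sided": res.p_two_sided, "method": res.method,
    }


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> RunReport:
    """Run the full synthetic analysis and return a deterministic report."""
    warnings: list[str] = []

    # stage 1: genome table
    genome_table = synth.synthetic_genome_table(seed=cfg.seed)
    survivors = filter_genomes(genome_table)

    # stage 2: tree + profiles
    true_tree = synth.random_tree(n_leaves=cfg.n_leaves, seed=cfg.seed)
    sim_cfg = synth.SimulationConfig(
        n_leaves=cfg.n_leaves,
        loss_rate=cfg.loss_rate,
        hgt_rate=cfg.hgt_rate,
        fp_rate=cfg.fp_rate,
        fn_rate=cfg.fn_rate,
        n_units=cfg.n_units,
        seed=cfg.seed + 7,
    )
    matrix, truth = synth.simulate_profiles(true_tree, sim_cfg)
    fold_map = synth.synthetic_fold_map(
        matrix.unit_ids, n_folds=cfg.n_folds, seed=cfg.seed + 11
    )
    matrices = {
        "superfamily": matrix,
        "fold": collapse_to_fold(matrix, fold_map),
    }

    # stage 3: trees
    trees = {}
    for method, level in cfg.tree_recipes():
        tree, warn = build_tree(method, level, matrices, true_tree, cfg)
        if warn:
            warnings.append(warn)
        trees[(method, level)] = tree

    # stage 4: ages (maximum parsimony on every tree)
    sk = synth.superkingdom_map(true_tree)
    euk_leaves = {lab for lab, s in sk.items() if s == "Eukarya"}
    ages_by_recipe: dict[str, dict[str, float]] = {}
    for (method, level), tree in trees.items():
        m = matrices[level]
        ages = {}
        for uid in m.unit_ids:
            ages[uid] = estimate_age(
                tree, m.profile(uid), model="mp", g=cfg.gain_weight, unit_id=uid
            ).age
        ages_by_recipe[f"{method}/{level}"] = ages
    sf_recipes = {
        k: v for k, v in ages_by_recipe.items() if k.endswith("/superfamily")
    }
    rho_sf = concordance(sf_recipes)

    # model agreement on the backbone superfamily tree
    ref_tree = trees[("backbone-wagner", "superfamily")]
    mp_ages, dollo_ages, fusion_ages, true_ages = {}, {}, {}, {}
    for uid in matrix.unit_ids:
        prof = matrix.profile(uid)
        mp_ages[uid] = estimate_age(
            ref_tree, prof, model="mp", g=cfg.gain_weight, unit_id=uid
        ).age
        dollo_ages[uid] = estimate_age(ref_tree, prof, model="dollo", unit_id=uid).age
        fusion_ages[uid] = estimate_age(
            ref_tree, prof, model="fusion", g=cfg.gain_weight,
            euk_leaves=euk_leaves, unit_id=uid,
        ).age
        true_ages[uid] = truth.units[uid].true_age
    model_rho = concordance(
        {"mp": mp_ages, "dollo": dollo_ages, "fusion": fusion_ages, "true": true_ages}
    )

    # stage 5: age groups
    cutoff = (
        auto_cutoff(mp_ages) if cfg.cutoff == "auto" else float(cfg.cutoff)
    )
    labels = assign_age_groups(mp_ages, cutoff=cutoff)
    groups = {l.unit_id: l.group for l in labels}
    group_sizes = dict(pd.Series(list(groups.values())).value_counts())
    group_sizes = {k: int(v) for k, v in group_sizes.items()}

    # stage 6: structures for a stratified subset of superfamilies
    rng = np.random.default_rng(cfg.seed + 23)
    by_group: dict[str, list[str]] = {"ancient": [], "middle": [], "newborn": []}
    for uid, g in groups.items():
        by_group[g].append(uid)
    chosen: list[tuple[str, float]] = []
    per_group = max(1, cfg.n_struct_superfamilies // 3)
    for g in ("ancient", "middle", "newborn"):
        pool = sorted(by_group[g])
        take = min(per_group, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False) if take else []
        chosen.extend((pool[int(i)], mp_ages[pool[int(i)]]) for i in idx)
    domains = _make_structures(chosen, seed=cfg.seed + 31)

    summaries = {
        sf: summarize_superfamily(doms) for sf, doms in domains.items()
    }
    desc_records = {
        sf: [describe_domain(d) for d in doms] for sf, doms in domains.items()
    }

    def contrast(attr: str):
        anc = [
            getattr(summaries[sf], attr)
            for sf in summaries if groups[sf] == "ancient"
        ]
        new = [
            getattr(summaries[sf], attr)
            for sf in summaries if groups[sf] == "newborn"
        ]
        if not anc or not new:
            return None
        return _mw_dict(mann_whitney_ties(anc, new))

    descriptor_contrasts = {
        "length": contrast("mean_length"),
        "nonlocal_contacts_norm": contrast("mean_nonlocal_norm"),
        "buried_norm": contrast("mean_buried_norm"),
        "hydrophobicity": contrast("mean_hydrophobicity"),
    }
    # disulphide contrast: ages of with- vs without-disulphide superfamilies
    ds_with = [
        mp_ages[sf] for sf, s in summaries.items() if s.disulphide_class == "with"
    ]
    ds_without = [
        mp_ages[sf] for sf, s in summaries.items() if s.disulphide_class == "without"
    ]
    if ds_with and ds_without:
        descriptor_contrasts["disulphide_age"] = _mw_dict(
            mann_whitney_ties(ds_with, ds_without)
        )

    # propensities: ancient vs newborn domain sequences
    seqs_by_group = {
        g: [
            d.sequence
            for sf in summaries
            if groups[sf] == g
            for d in domains[sf]
        ]
        for g in ("ancient", "newborn")
    }
    background = [d.sequence for doms in domains.values() for d in doms]
    prop_df = amino_acid_propensities(seqs_by_group, background=background)
    propensities = {
        "n_amino_acids": int(prop_df["amino_acid"].nunique()),
        "max_propensity": float(prop_df["propensity"].max()),
        "min_propensity": float(prop_df["propensity"].min()),
    }

    # stage 7: motifs
    calls_by_sf = {}
    for sf, doms in domains.items():
        calls = []
        for d in doms:
            if d.sheet_topology is not None:
                calls.extend(detect_motifs(d.sheet_topology, domain_id=d.domain_id))
        calls_by_sf[sf] = calls
    greek_set, jelly_set = classify_superfamily_motifs(calls_by_sf)
    motif_report = {
        "greek_key_superfamilies": len(greek_set),
        "jelly_roll_superfamilies": len(jelly_set),
    }
    if greek_set and jelly_set:
        motif_report["age_contrast"] = _mw_dict(
            mann_whitney_ties(
                [mp_ages[sf] for sf in greek_set],
                [mp_ages[sf] for sf in jelly_set],
            )
        )

    # stage 8: functional annotations and enrichment
    planted = [
        (f"T{k:04d}", "ancient", 0.6, 0.08)
        for k in range(cfg.n_go_terms_planted)
    ]
    planted += [("T9001", "middle", 0.5, 0.05)]
    planted += [
        (f"T8{k:03d}", "newborn", 0.1, 0.1) for k in range(5)
    ]  # null terms: no real enrichment anywhere
    annotations = synth.synthetic_go(
        matrix.unit_ids, groups, planted, seed=cfg.seed + 41
    )
    enrich = hypergeometric_enrichment(annotations, groups, alpha=cfg.alpha)
    sig = [r for r in enrich if r.significant]
    enrichment = {
        "n_tests": len(enrich),
        "n_terms": len({r.term_id for r in enrich}),
        "n_significant": len(sig),
        "significant_by_group": {
            g: len({r.term_id for r in sig if r.group == g})
            for g in ("ancient", "middle", "newborn")
        },
    }

    # structure vs function: terms tied to the strand labels
    strand_labels = {sf: s.strand_label for sf, s in summaries.items()}
    svf_terms = [
        ("TPAR0", "parallel", 0.7, 0.05),
        ("TPAR1", "parallel", 0.6, 0.05),
        ("TANTI0", "antiparallel", 0.7, 0.05),
        ("TANTI1", "antiparallel", 0.6, 0.05),
    ]
    svf_annotations = synth.synthetic_go(
        sorted(summaries), strand_labels, svf_terms, seed=cfg.seed + 43
    )
    struct_ages = {sf: mp_ages[sf] for sf in summaries}
    try:
        svf = structure_vs_function_contrast(
            struct_ages, strand_labels, svf_annotations, alpha=cfg.alpha
        )
        contrast_report = {
            "structural": _mw_dict(svf.structural),
            "functional": _mw_dict(svf.functional) if svf.functional else None,
            "functional_unique": (
                _mw_dict(svf.functional_unique) if svf.functional_unique else None
            ),
            "n_parallel_terms": svf.n_parallel_terms,
            "n_antiparallel_terms": svf.n_antiparallel_terms,
            "n_overlap_superfamilies": svf.n_overlap_superfamilies,
            "notes": svf.notes,
        }
    except ValueError as exc:
        contrast_report = {"error": str(exc)}
        warnings.append(f"structure-vs-function contrast skipped: {exc}")

    counts = {
        "genomes_total": len(genome_table),
        "genomes_after_filtering": len(survivors),
        "tree_configurations": len(cfg.tree_recipes()),
        "units_superfamily": len(matrix.unit_ids),
        "units_fold": len(matrices["fold"].unit_ids),
        "units_redrawn": truth.n_redraws,
        "aged_units": len(mp_ages),
        "struct_superfamilies": len(summaries),
        "cutoff": cutoff,
    }
    report = RunReport(
        params={
            "seed": cfg.seed,
            "n_leaves": cfg.n_leaves,
            "n_units": cfg.n_units,
            "loss_rate": cfg.loss_rate,
            "hgt_rate": cfg.hgt_rate,
            "fp_rate": cfg.fp_rate,
            "fn_rate": cfg.fn_rate,
            "gain_weight": cfg.gain_weight,
            "n_jackknife": cfg.n_jackknife,
        },
        counts=counts,
        group_sizes=group_sizes,
        tree_warnings=warnings,
        concordance_superfamily={
            r: {c: float(rho_sf.loc[r, c]) for c in rho_sf.columns}
            for r in rho_sf.index
        },
        model_agreement={
            r: {c: float(model_rho.loc[r, c]) for c in model_rho.columns}
            for r in model_rho.index
        },
        descriptor_contrasts=descriptor_contrasts,
        propensities=propensities,
        enrichment=enrichment,
        motifs=motif_report,
        contrast=contrast_report,
    )
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        matrix.to_tsv(os.path.join(out_dir, "occurrence_superfamily.tsv"))
        matrices["fold"].to_tsv(os.path.join(out_dir, "occurrence_fold.tsv"))
        for (method, level), tree in trees.items():
            tree.write(
                path=os.path.join(out_dir, f"tree_{method}_{level}.nwk"),
                schema="newick",
                suppress_rooting=True,
            )
        pd.Series(mp_ages, name="age").rename_axis("unit_id").to_csv(
            os.path.join(out_dir, "ages_mp.tsv"), sep="\t"
        )
        report.to_json(os.path.join(out_dir, "report.json"))
    return report
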