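"""Structural and sequence descriptors of representative domains.

Each domain is represented by its Calpha trace, its amino-acid sequence
and per-residue annotations (secondary-structure element, relative
solvent exposure in percent, disulphide partner) as produced upstream by
structure-annotation tools; this module only consumes those annotations.

Descriptors follow the conventions used to contrast new-born and ancient
superfamily populations: radius of gyration; non-local contact count
normalised by the radius of gyration; buried-residue fraction normalised
by the radius of gyration; mean hydrophobicity on the optimal matching
hydrophobicity (OMH) scale of Sweet & Eisenberg; parallel/antiparallel
strand-direction labels; disulphide-bond classes; and per-amino-acid
propensities of age groups relative to the whole domain set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from foldspace.motifs import SheetTopology

SS_ELEMENTS = ("helix", "strand", "coil")

# descriptor defaults; the contact and burial thresholds follow common
# Calpha contact-order and structure-annotation conventions and are
# configurable everywhere they are used
DEFAULT_CONTACT_THRESHOLD = 8.0   # Angstrom, Calpha-Calpha
DEFAULT_MIN_SEPARATION = 5        # residues, |i - j| for a non-local contact
DEFAULT_BURIAL_THRESHOLD = 7.0    # percent relative exposure
DEFAULT_MIN_STRAND_CONTENT = 0.15
DEFAULT_MAJORITY_THRESHOLD = 0.7


@dataclass(frozen=True)
class ResidueAnnotation:
    ss_element: str
    strand_id: str | None = None
    relative_exposure: float | None = None
    disulphide_partner: int | None = None


@dataclass
class DomainStructure:
    """One representative domain: sequence, Calpha trace and annotations."""

    domain_id: str
    superfamily_id: str
    sequence: str
    ca_coords: np.ndarray
    annotations: list[ResidueAnnotation]
    sheet_topology: SheetTopology | None = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        n = len(self.sequence)
        if self.ca_coords.shape != (n, 3):
            raise ValueError(
                f"{self.domain_id}: expected {n}x3 coordinates, "
                f"got {self.ca_coords.shape}"
            )
        if len(self.annotations) != n:
            raise ValueError(f"{self.domain_id}: annotation length mismatch")
        for ann in self.annotations:
            if ann.ss_element not in SS_ELEMENTS:
                raise ValueError(f"unknown ss element {ann.ss_element!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_disulphide(self) -> bool:
        return any(a.disulphide_partner is not None for a in self.annotations)


@dataclass(frozen=True)
class DescriptorRecord:
    domain_id: str
    superfamily_id: str
    length: int
    rg: float
    total_contacts: int
    nonlocal_contacts: int
    nonlocal_contacts_norm: float
    buried_norm: float
    hydrophobicity: float
    strand_label: str
    has_disulphide: bool


@dataclass(frozen=True)
class SuperfamilySummary:
    superfamily_id: str
    n_domains: int
    mean_length: float
    mean_rg: float
    mean_nonlocal_norm: float
    mean_buried_norm: float
    mean_hydrophobicity: float
    strand_label: str
    disulphide_class: str


# ---------------------------------------------------------------------------
# geometry


def radius_of_gyration(coords: np.ndarray) -> float:
    """Root-mean-square distance of the Calpha atoms from their centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2 or coords.shape[1] != 3:
        raise ValueError("need at least two 3D points")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def contact_counts(
    coords: np.ndarray,
    dist_threshold: float = DEFAULT_CONTACT_THRESHOLD,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> tuple[int, int]:
    """Count residue contacts (total, non-local).

    Residues i < j are in contact when their Calpha atoms lie within
    ``dist_threshold`` Angstrom; a contact is non-local when
    ``j - i >= min_separation``.
    """
    if dist_threshold <= 0 or min_separation <= 0:
        raise ValueError("thresholds must be positive")
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    iu, ju = np.triu_indices(n, k=1)
    close = dist[iu, ju] <= dist_threshold
    nonlocal_mask = close & ((ju - iu) >= min_separation)
    return int(close.sum()), int(nonlocal_mask.sum())


def nonlocal_contacts_norm(
    domain: DomainStructure,
    dist_threshold: float = DEFAULT_CONTACT_THRESHOLD,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> float:
    """Non-local contact count divided by the radius of gyration."""
    rg = radius_of_gyration(domain.ca_coords)
    if rg == 0.0:
        raise ValueError("radius of gyration is zero")
    _total, nonloc = contact_counts(domain.ca_coords, dist_threshold, min_separation)
    return nonloc / rg


def buried_fraction_norm(
    domain: DomainStructure,
    exposure_threshold: float = DEFAULT_BURIAL_THRESHOLD,
    raw_count: bool = False,
) -> float:
    """Buried-residue proportion divided by the radius of gyration.

    A residue is buried when its relative solvent exposure is below
    ``exposure_threshold`` percent.  With ``raw_count=True`` the raw
    buried count, rather than the proportion, is normalised.
    """
    missing = [
        i for i, a in enumerate(domain.annotations) if a.relative_exposure is None
    ]
    if missing:
        raise ValueError(f"missing exposure for residues {missing}")
    rg = radius_of_gyration(domain.ca_coords)
    if rg == 0.0:
        raise ValueError("radius of gyration is zero")
    buried = sum(
        1 for a in domain.annotations if a.relative_exposure < exposure_threshold
    )
    value = buried if raw_count else buried / len(domain)
    return value / rg


# ---------------------------------------------------------------------------
# sequence


def load_omh_scale(path=None) -> dict[str, float]:
    """Load a residue -> hydrophobicity table (default: the OMH scale)."""
    if path is None:
        with resources.files("foldspace.data").joinpath("omh_scale.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["residue"], df["value"].astype(float)))


_OMH: dict[str, float] | None = None


def _omh() -> dict[str, float]:
    global _OMH
    if _OMH is None:
        _OMH = load_omh_scale()
    return _OMH


def hydrophobicity(
    sequence: str,
    scale: Mapping[str, float] | None = None,
    map_unknown_to_mean: bool = False,
) -> float:
    """Mean per-residue hydrophobicity of a sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    scale = dict(scale) if scale is not None else _omh()
    mean_val = float(np.mean(list(scale.values())))
    total = 0.0
    for aa in sequence:
        if aa in scale:
            total += scale[aa]
        elif map_unknown_to_mean:
            total += mean_val
        else:
            raise KeyError(f"residue {aa!r} not in hydrophobicity scale")
    return total / len(sequence)


# ---------------------------------------------------------------------------
# strand direction and disulphides


def strand_direction_label(
    domain: DomainStructure,
    min_strand_content: float = DEFAULT_MIN_STRAND_CONTENT,
    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
) -> str:
    """Label a domain parallel / antiparallel / mixed / not_applicable.

    Each strand residue inherits the orientations of its strand's sheet
    pairings (a strand paired both ways contributes to both tallies).
    Domains whose strand-residue fraction is below ``min_strand_content``
    are not labelled.
    """
    n = len(domain)
    strand_res = [
        (i, a.strand_id) for i, a in enumerate(domain.annotations)
        if a.ss_element == "strand"
    ]
    if n == 0 or len(strand_res) / n < min_strand_content:
        return "not_applicable"
    topo = domain.sheet_topology
    orientations: dict[str, list[str]] = {}
    if topo is not None:
        for pa, pb, orient in topo.pairings:
            orientations.setdefault(pa, []).append(orient)
            orientations.setdefault(pb, []).append(orient)
    par = 0.0
    anti = 0.0
    for _i, sid in strand_res:
        for orient in orientations.get(sid, []):
            if orient == "parallel":
                par += 1.0
            else:
                anti += 1.0
    total = par + anti
    if total == 0:
        return "mixed"
    if par / total >= majority_threshold:
        return "parallel"
    if anti / total >= majority_threshold:
        return "antiparallel"
    return "mixed"


def disulphide_class(domains: Sequence[DomainStructure]) -> str:
    """Classify a superfamily's disulphide status from its domains.

    ``with`` when more than half the representative domains contain at
    least one disulphide bond; ``without`` only when none do; the
    remaining middle class is ``ambiguous`` and is excluded from the
    with/without contrast.
    """
    if not domains:
        raise ValueError("need at least one domain")
    n_with = sum(1 for d in domains if d.has_disulphide)
    if n_with == 0:
        return "without"
    if n_with > len(domains) / 2:
        return "with"
    return "ambiguous"


# ---------------------------------------------------------------------------
# propensities


def amino_acid_propensities(
    sequences_by_group: Mapping[str, Sequence[str]],
    background: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Amino-acid propensities of groups relative to the whole set.

    P(aa, group) = (n_aa,group / N_group) / (n_aa / N), with counts over
    all residues of all sequences.  ``background`` defaults to the union
    of the groups; pass the full domain set explicitly when the groups
    are a subset of it.  Amino acids absent from the background have
    undefined propensity and are reported as NaN.  Chi-square
    significance per cell comes from
    :func:`foldspace.stats.chi_square_propensity`.
    """
    from foldspace.stats import chi_square_propensity

    if background is None:
        background = [s for seqs in sequences_by_group.values() for s in seqs]
    bg_counts: Counter[str] = Counter()
    for s in background:
        bg_counts.update(s)
    N = sum(bg_counts.values())
    if N == 0:
        raise ValueError("empty background")
    rows = []
    for group, seqs in sequences_by_group.items():
        gc: Counter[str] = Counter()
        for s in seqs:
            gc.update(s)
        n_group = sum(gc.values())
        for aa in sorted(bg_counts):
            n_aa = bg_counts[aa]
            k = gc.get(aa, 0)
            prop = (k / n_group) / (n_aa / N) if n_group else float("nan")
            p = chi_square_propensity(k, n_group, n_aa, N).p if n_group else float("nan")
            rows.append(
                {
                    "amino_acid": aa,
                    "group": group,
                    "count_group": k,
                    "total_group": n_group,
                    "count_overall": n_aa,
                    "total_overall": N,
                    "propensity": prop,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-domain and per-superfamily aggregation


def describe_domain(
    domain: DomainStructure,
    dist_threshold: float = DEFAULT_CONTACT_THRESHOLD,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    exposure_threshold: float = DEFAULT_BURIAL_THRESHOLD,
    min_strand_content: float = DEFAULT_MIN_STRAND_CONTENT,
    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
    scale: Mapping[str, float] | None = None,
) -> DescriptorRecord:
    """Compute the full descriptor suite for one domain."""
    rg = radius_of_gyration(domain.ca_coords)
    total, nonloc = contact_counts(domain.ca_coords, dist_threshold, min_separation)
    return DescriptorRecord(
        domain_id=domain.domain_id,
        superfamily_id=domain.superfamily_id,
        length=len(domain),
        rg=rg,
        total_contacts=total,
        nonlocal_contacts=nonloc,
        nonlocal_contacts_norm=nonloc / rg,
        buried_norm=buried_fraction_norm(domain, exposure_threshold),
        hydrophobicity=hydrophobicity(domain.sequence, scale=scale),
        strand_label=strand_direction_label(
            domain, min_strand_content, majority_threshold
        ),
        has_disulphide=domain.has_disulphide,
    )


def summarize_superfamily(
    domains: Sequence[DomainStructure],
    records: Sequence[DescriptorRecord] | None = None,
    **kwargs,
) -> SuperfamilySummary:
    """Aggregate domain descriptors to superfamily level.

    Numeric descriptors are averaged; the strand label is the strict
    majority over labelled domains (``mixed`` on ties).
    """
    if not domains:
        raise ValueError("need at least one domain")
    sf = {d.superfamily_id for d in domains}
    if len(sf) != 1:
        raise ValueError(f"domains span several superfamilies: {sorted(sf)}")
    if records is None:
        records = [describe_domain(d, **kwargs) for d in domains]
    labels = [r.strand_label for r in records if r.strand_label != "not_applicable"]
    if labels:
        counts = Counter(labels)
        top, top_n = counts.most_common(1)[0]
        label = top if list(counts.values()).count(top_n) == 1 else "mixed"
    else:
        label = "not_applicable"
    return SuperfamilySummary(
        superfamily_id=sf.pop(),
        n_domains=len(domains),
        mean_length=float(np.mean([r.length for r in records])),
        mean_rg=float(np.mean([r.rg for r in records])),
        mean_nonlocal_norm=float(np.mean([r.nonlocal_contacts_norm for r in records])),
        mean_buried_norm=float(np.mean([r.buried_norm for r in records])),
        mean_hydrophobicity=float(np.mean([r.hydrophobicity for r in records])),
        strand_label=label,
        disulphide_class=disulphide_class(domains),
    )


# ---------------------------------------------------------------------------
# I/O


def read_ca_pdb(path, domain_id: str = "", superfamily_id: str = "") -> tuple[str, np.ndarray]:
    """Read one-letter sequence and Calpha coordinates from a PDB file.

    Uses the first model, first chain and first altloc; only CA atoms of
    standard residues are considered.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(domain_id or "domain", str(path))
    model = next(structure.get_models())
    chain = next(model.get_chains())
    seq = []
    coords = []
    for residue in chain.get_residues():
        if residue.id[0].strip():
            continue  # hetero/water
        if "CA" not in residue:
            continue
        atom = residue["CA"]
        if atom.is_disordered():
            atom = atom.disordered_get_list()[0]
        name = residue.get_resname().upper()
        seq.append(protein_letters_3to1.get(name, "X"))
        coords.append(atom.get_coord())
    return "".join(seq), np.asarray(coords, dtype=float)


def read_annotations(path) -> list[ResidueAnnotation]:
    """Read a per-residue annotation TSV.

    Columns: residue_index, aa, ss_element, strand_id, relative_exposure,
    disulphide_partner (blank for none).
    """
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("residue_index")
    out = []
    for row in df.itertuples(index=False):
        sid = getattr(row, "strand_id", None)
        sid = None if pd.isna(sid) else str(sid)
        partner = getattr(row, "disulphide_partner", None)
        partner = None if pd.isna(partner) else int(partner)
        exposure = getattr(row, "relative_exposure", None)
        exposure = None if pd.isna(exposure) else float(exposure)
        out.append(
            ResidueAnnotation(
                ss_element=str(row.ss_element),
                strand_id=sid,
                relative_exposure=exposure,
                disulphide_partner=partner,
            )
        )
    return out


def write_descriptors(records: Sequence[DescriptorRecord], path) -> None:
    # %.17g keeps the round trip lossless for doubles
    pd.DataFrame([r.__dict__ for r in records]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_descriptors(path) -> list[DescriptorRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        DescriptorRecord(
            domain_id=str(r.domain_id),
            superfamily_id=str(r.superfamily_id),
            length=int(r.length),
            rg=float(r.rg),
            total_contacts=int(r.total_contacts),
            nonlocal_contacts=int(r.nonlocal_contacts),
            nonlocal_contacts_norm=float(r.nonlocal_contacts_norm),
            buried_norm=float(r.buried_norm),
            hydrophobicity=float(r.hydrophobicity),
            strand_label=str(r.strand_label),
            has_disulphide=bool(r.has_disulphide),
        )
        for r in df.itertuples(index=False)
    ]
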