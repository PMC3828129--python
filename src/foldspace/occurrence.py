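"""Binary occurrence profiles of structural units across genomes.

A superfamily's occurrence profile is the binary vector of its presence or
absence on each completely sequenced genome.  This module builds the
units x genomes occurrence matrix from raw per-genome assignment lists,
filters genome metadata tables (pathogens, *candidatus* taxa, manual
removals), collapses superfamily matrices to the fold level, and computes
the two binary dissimilarities (Jaccard, Bray-Curtis) used to build
whole-genome distance trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUPERKINGDOMS = ("Archaea", "Bacteria", "Eukarya")


@dataclass(frozen=True)
class GenomeRecord:
    """Metadata for one completely sequenced genome."""

    genome_id: str
    superkingdom: str
    multicellular: bool = False
    pathogen: bool = False
    candidatus: bool = False
    manual_remove: bool = False

    def __post_init__(self) -> None:
        if self.superkingdom not in SUPERKINGDOMS:
            raise ValueError(
                f"superkingdom must be one of {SUPERKINGDOMS}, "
                f"got {self.superkingdom!r}"
            )


@dataclass(frozen=True)
class ContingencyCounts:
    """Unit sharing counts between two genomes.

    ``a`` units present on both, ``b`` only on the first, ``c`` only on the
    second.  Units absent from both genomes are ignored throughout.
    """

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("contingency counts must be non-negative")


@dataclass
class OccurrenceMatrix:
    """Binary units x genomes presence/absence matrix.

    ``df`` is indexed by unit id (superfamily or fold identifier) with one
    column per genome id; values are 0/1 integers.
    """

    df: pd.DataFrame
    level: str = "superfamily"

    def __post_init__(self) -> None:
        if self.level not in ("superfamily", "fold"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.df.index.has_duplicates:
            raise ValueError("duplicate unit ids")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate genome ids")
        vals = self.df.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("occurrence values must be 0 or 1")
        self.df = self.df.astype(np.int8)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.columns)

    def profile(self, unit_id: str) -> dict[str, int]:
        """Presence/absence of one unit as a genome_id -> {0,1} mapping."""
        return self.df.loc[unit_id].to_dict()

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="unit_id")

    @classmethod
    def from_tsv(cls, path, level: str = "superfamily") -> "OccurrenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df=df, level=level)


@dataclass
class DistanceMatrix:
    """Symmetric genome x genome dissimilarity matrix in [0, 1]."""

    df: pd.DataFrame
    metric: str

    def __post_init__(self) -> None:
        d = self.df.to_numpy(dtype=float)
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if d.size and (d.min() < -1e-12 or d.max() > 1 + 1e-12):
            raise ValueError("distances must lie in [0, 1]")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.columns)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="genome_id")


# ---------------------------------------------------------------------------
# genome metadata


def read_genome_table(path) -> list[GenomeRecord]:
    """Read a genome metadata TSV (genome_id, superkingdom, flag columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GenomeRecord(
                genome_id=row.genome_id,
                superkingdom=row.superkingdom,
                multicellular=bool(getattr(row, "multicellular", False)),
                pathogen=bool(getattr(row, "pathogen", False)),
                candidatus=bool(getattr(row, "candidatus", False)),
                manual_remove=bool(getattr(row, "manual_remove", False)),
            )
        )
    return records


def write_genome_table(records: Sequence[GenomeRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "superkingdom": r.superkingdom,
                "multicellular": r.multicellular,
                "pathogen": r.pathogen,
                "candidatus": r.candidatus,
                "manual_remove": r.manual_remove,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def filter_genomes(
    records: Sequence[GenomeRecord],
    drop_pathogen: bool = True,
    drop_candidatus: bool = True,
    drop_manual: bool = True,
) -> list[GenomeRecord]:
    """Drop flagged genomes, preserving input order.

    A genome flagged in several enabled categories is removed once (set
    union semantics); the input list is not modified.
    """
    if not records:
        raise ValueError("empty genome table")
    out = [
        r
        for r in records
        if not (
            (drop_pathogen and r.pathogen)
            or (drop_candidatus and r.candidatus)
            or (drop_manual and r.manual_remove)
        )
    ]
    if not out:
        logger.warning("genome filtering removed every record")
    return out


# ---------------------------------------------------------------------------
# matrix construction


def build_matrix(
    assignments: Iterable[tuple[str, str]],
    genomes: Sequence[GenomeRecord] | Sequence[str],
    level: str = "superfamily",
    unit_ids: Sequence[str] | None = None,
) -> OccurrenceMatrix:
    """Collapse (genome_id, unit_id) assignment pairs to a binary matrix.

    Duplicate assignments collapse to a single presence.  ``unit_ids`` may
    declare the row universe explicitly (units never assigned get all-zero
    rows); otherwise rows are the units seen in the assignments, sorted.
    """
    genome_ids = [g.genome_id if isinstance(g, GenomeRecord) else g for g in genomes]
    if len(set(genome_ids)) != len(genome_ids):
        raise ValueError("duplicate genome ids")
    known = set(genome_ids)
    pairs = list(assignments)
    for g, _u in pairs:
        if g not in known:
            raise KeyError(f"assignment references unknown genome id {g!r}")
    if unit_ids is None:
        unit_ids = sorted({u for _g, u in pairs})
    df = pd.DataFrame(0, index=list(unit_ids), columns=genome_ids, dtype=np.int8)
    for g, u in pairs:
        df.loc[u, g] = 1
    return OccurrenceMatrix(df=df, level=level)


def collapse_to_fold(
    m: OccurrenceMatrix, sf_to_fold: Mapping[str, str]
) -> OccurrenceMatrix:
    """Collapse a superfamily matrix to fold level by OR over member rows."""
    if m.level != "superfamily":
        raise ValueError("collapse_to_fold expects a superfamily-level matrix")
    missing = [u for u in m.unit_ids if u not in sf_to_fold]
    if missing:
        raise KeyError(f"superfamilies not mapped to a fold: {missing}")
    folds = pd.Index([sf_to_fold[u] for u in m.unit_ids], name="unit_id")
    collapsed = (m.df.groupby(folds).max()).astype(np.int8)
    return OccurrenceMatrix(df=collapsed, level="fold")


# ---------------------------------------------------------------------------
# dissimilarities


def contingency(m: OccurrenceMatrix, gi: str, gj: str) -> ContingencyCounts:
    """Count units shared by and private to a pair of genomes."""
    for g in (gi, gj):
        if g not in m.df.columns:
            raise KeyError(f"unknown genome id {g!r}")
    x = m.df[gi].to_numpy()
    y = m.df[gj].to_numpy()
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    return ContingencyCounts(a=a, b=b, c=c)


def jaccard_distance(cc: ContingencyCounts) -> float:
    """Binary Jaccard dissimilarity (b + c) / (a + b + c)."""
    n = cc.a + cc.b + cc.c
    if n == 0:
        raise ValueError("no shared universe: both profiles are empty")
    return (cc.b + cc.c) / n


def bray_curtis_distance(cc: ContingencyCounts) -> float:
    """Bray-Curtis dissimilarity on presence/absence, (b + c) / (2a + b + c)."""
    n = 2 * cc.a + cc.b + cc.c
    if n == 0:
        raise ValueError("no shared universe: both profiles are empty")
    return (cc.b + cc.c) / n


_METRICS = {"jaccard": jaccard_distance, "braycurtis": bray_curtis_distance}


def distance_matrix(m: OccurrenceMatrix, metric: str = "jaccard") -> DistanceMatrix:
    """All-pairs genome dissimilarity matrix under the chosen metric."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if len(m.genome_ids) < 3:
        raise ValueError("need at least 3 genomes for a distance matrix")
    x = m.df.to_numpy(dtype=np.int64)  # units x genomes
    a = x.T @ x
    present = x.sum(axis=0)
    b = present[:, None] - a
    c = present[None, :] - a
    if metric == "jaccard":
        denom = a + b + c
    else:
        denom = 2 * a + b + c
    bad = np.argwhere((denom == 0) & ~np.eye(len(present), dtype=bool))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            "empty unit union between genomes "
            f"{m.genome_ids[i]!r} and {m.genome_ids[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(denom > 0, (b + c) / np.maximum(denom, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    df = pd.DataFrame(d, index=m.genome_ids, columns=m.genome_ids)
    return DistanceMatrix(df=df, metric=metric)
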