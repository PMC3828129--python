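"""Greek key and jelly roll motif detection in beta-sheet topologies.

A sheet topology records, for each strand, its rank along the chain
(sequence order) and its integer slot in the sheet (spatial position),
plus the orientation of each pairing between spatially adjacent strands.
Hydrogen-bond partners and strand assignments come from upstream
structure annotation; this module only analyses the recorded topology.

A greek key is a window of four sequence-consecutive strands in one
sheet, all pairings antiparallel, whose spatial-position deltas match a
signature (default +3,-1,-1 or its mirror -3,+1,+1): the first
connection spans three strand positions.  A jelly roll is a greek key
wrapped by two further strands, one preceding and one following the key
in sequence, sitting on the two outer spatial slots and pairing
antiparallel with the key's outer strands.  Signatures are data, not
code, and may be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_GREEK_KEY_SIGNATURES: tuple[tuple[int, int, int], ...] = (
    (3, -1, -1),
    (-3, 1, 1),
)


@dataclass(frozen=True)
class Strand:
    strand_id: str
    sequence_order: int
    spatial_position: int


@dataclass
class SheetTopology:
    """Spatial arrangement and pairings of the strands of one sheet."""

    sheet_id: str
    strands: list[Strand]
    pairings: list[tuple[str, str, str]]  # (strand_a, strand_b, orientation)

    def __post_init__(self) -> None:
        positions = [s.spatial_position for s in self.strands]
        if len(set(positions)) != len(positions):
            raise ValueError(f"sheet {self.sheet_id}: duplicate spatial positions")
        ids = {s.strand_id for s in self.strands}
        pos = {s.strand_id: s.spatial_position for s in self.strands}
        for a, b, orient in self.pairings:
            if a not in ids or b not in ids:
                raise ValueError(f"pairing references unknown strand {a!r}/{b!r}")
            if abs(pos[a] - pos[b]) != 1:
                raise ValueError(
                    f"pairing {a}-{b} joins non-adjacent spatial positions"
                )
            if orient not in ("parallel", "antiparallel"):
                raise ValueError(f"unknown orientation {orient!r}")

    def orientation(self, a: str, b: str) -> str | None:
        for pa, pb, orient in self.pairings:
            if {pa, pb} == {a, b}:
                return orient
        return None


@dataclass(frozen=True)
class MotifCall:
    domain_id: str
    motif: str  # greek_key | jelly_roll
    strand_ids: tuple[str, ...]


def _sequence_sorted(topology: SheetTopology) -> list[Strand]:
    return sorted(topology.strands, key=lambda s: s.sequence_order)


def find_greek_keys(
    topology: SheetTopology,
    domain_id: str = "",
    signatures: Iterable[tuple[int, int, int]] = DEFAULT_GREEK_KEY_SIGNATURES,
) -> list[MotifCall]:
    """Scan every 4-strand sequence-consecutive window for a greek key."""
    signatures = set(tuple(s) for s in signatures)
    strands = _sequence_sorted(topology)
    calls = []
    for i in range(len(strands) - 3):
        window = strands[i : i + 4]
        orders = [s.sequence_order for s in window]
        if orders != list(range(orders[0], orders[0] + 4)):
            continue  # not sequence-consecutive
        deltas = tuple(
            window[k + 1].spatial_position - window[k].spatial_position
            for k in range(3)
        )
        if deltas not in signatures:
            continue
        # every pairing between spatially adjacent window strands must be
        # antiparallel and present
        ok = True
        by_pos = sorted(window, key=lambda s: s.spatial_position)
        for a, b in zip(by_pos, by_pos[1:]):
            if topology.orientation(a.strand_id, b.strand_id) != "antiparallel":
                ok = False
                break
        if ok:
            calls.append(
                MotifCall(
                    domain_id=domain_id,
                    motif="greek_key",
                    strand_ids=tuple(s.strand_id for s in window),
                )
            )
    return calls


def find_jelly_rolls(
    topology: SheetTopology,
    greek_keys: Sequence[MotifCall],
    domain_id: str = "",
) -> list[MotifCall]:
    """Detect jelly rolls: a greek key wrapped by two outer strands.

    The wrapping strands immediately precede and follow the key in
    sequence, occupy the spatial slots just outside the key's occupied
    span (in either assignment), and pair antiparallel with their
    spatially adjacent key strands.
    """
    strands = _sequence_sorted(topology)
    by_id = {s.strand_id: s for s in topology.strands}
    order_index = {s.strand_id: k for k, s in enumerate(strands)}
    calls = []
    for key in greek_keys:
        if key.motif != "greek_key":
            continue
        idx = [order_index[sid] for sid in key.strand_ids]
        first, last = min(idx), max(idx)
        if first == 0 or last == len(strands) - 1:
            continue  # no strand before/after the key in sequence
        before = strands[first - 1]
        after = strands[last + 1]
        slots = [by_id[sid].spatial_position for sid in key.strand_ids]
        lo, hi = min(slots) - 1, max(slots) + 1
        wrap_slots = {before.spatial_position, after.spatial_position}
        if wrap_slots != {lo, hi}:
            continue
        ok = True
        for wrapper in (before, after):
            # the key strand on the adjacent slot
            target_slot = (
                wrapper.spatial_position + 1
                if wrapper.spatial_position == lo
                else wrapper.spatial_position - 1
            )
            partner = next(
                (sid for sid in key.strand_ids
                 if by_id[sid].spatial_position == target_slot),
                None,
            )
            if partner is None or topology.orientation(
                wrapper.strand_id, partner
            ) != "antiparallel":
                ok = False
                break
        if ok:
            calls.append(
                MotifCall(
                    domain_id=domain_id,
                    motif="jelly_roll",
                    strand_ids=(before.strand_id, *key.strand_ids, after.strand_id),
                )
            )
    return calls


def detect_motifs(
    topology: SheetTopology,
    domain_id: str = "",
    signatures: Iterable[tuple[int, int, int]] = DEFAULT_GREEK_KEY_SIGNATURES,
) -> list[MotifCall]:
    """Greek key and jelly roll calls for one sheet topology."""
    gk = find_greek_keys(topology, domain_id=domain_id, signatures=signatures)
    jr = find_jelly_rolls(topology, gk, domain_id=domain_id)
    return gk + jr


def classify_superfamily_motifs(
    calls_by_superfamily: Mapping[str, Sequence[MotifCall]],
) -> tuple[set[str], set[str]]:
    """Partition superfamilies into jelly-roll and greek-key sets.

    A superfamily with a jelly roll in any representative domain joins
    the jelly-roll set; all remaining superfamilies with a greek key in
    any domain form the greek-key set.  The sets are disjoint.
    """
    jelly, greek = set(), set()
    for sf, calls in calls_by_superfamily.items():
        motifs = {c.motif for c in calls}
        if "jelly_roll" in motifs:
            jelly.add(sf)
        elif "greek_key" in motifs:
            greek.add(sf)
    return greek, jelly


# ---------------------------------------------------------------------------
# I/O


def read_topology_tsv(path) -> dict[str, SheetTopology]:
    """Read sheet topologies from TSV.

    Strand rows: record_type=strand, sheet_id, strand_id, sequence_order,
    spatial_position.  Pairing rows: record_type=pairing, sheet_id,
    strand_a, strand_b, orientation.
    """
    df = pd.read_csv(path, sep="\t")
    sheets: dict[str, SheetTopology] = {}
    for sheet_id, grp in df.groupby("sheet_id"):
        strands = [
            Strand(
                strand_id=str(r.strand_id),
                sequence_order=int(r.sequence_order),
                spatial_position=int(r.spatial_position),
            )
            for r in grp[grp.record_type == "strand"].itertuples(index=False)
        ]
        pairings = [
            (str(r.strand_a), str(r.strand_b), str(r.orientation))
            for r in grp[grp.record_type == "pairing"].itertuples(index=False)
        ]
        sheets[str(sheet_id)] = SheetTopology(
            sheet_id=str(sheet_id), strands=strands, pairings=pairings
        )
    return sheets


def write_topology_tsv(topologies: Iterable[SheetTopology], path) -> None:
    rows = []
    for topo in topologies:
        for s in topo.strands:
            rows.append(
                {
                    "record_type": "strand",
                    "sheet_id": topo.sheet_id,
                    "strand_id": s.strand_id,
                    "sequence_order": s.sequence_order,
                    "spatial_position": s.spatial_position,
                    "strand_a": "",
                    "strand_b": "",
                    "orientation": "",
                }
            )
        for a, b, orient in topo.pairings:
            rows.append(
                {
                    "record_type": "pairing",
                    "sheet_id": topo.sheet_id,
                    "strand_id": "",
                    "sequence_order": "",
                    "spatial_position": "",
                    "strand_a": a,
                    "strand_b": b,
                    "orientation": orient,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_motif_calls(calls: Iterable[MotifCall], path) -> None:
    pd.DataFrame(
        [
            {
                "domain_id": c.domain_id,
                "motif": c.motif,
                "strand_ids": ",".join(c.strand_ids),
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)
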