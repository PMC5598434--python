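"""Intron position homology and phase analysis for T2/S-RNases.

Land-plant T2/S-RNases carry introns at eleven positionally homologous
sites.  Two introns from different genes are treated as the same
position when their starting points fall within a seven-nucleotide
window of the codon-aware alignment (|column difference| <= 6,
single-linkage).  Introns are further classified by phase: phase 0
introns sit before the first base of a codon, phase 1 and 2 introns
interrupt a codon after its first or second base.  Within a homologous
position the phase is expected to be invariant; conflicts are recorded,
never silently merged.

Presence/absence of the canonical positions defines a small catalog of
named patterns: class I uses I-A {2}, I-B {5}, I-C {2,5} and I-D
{2,5,9}; class II always carries the eight introns {3,4,5,6,7,8,10,11};
class III uses III-A {5,9}, III-B* {9} (provisional, genome-predicted
only), III-C {5} and III-D {1,5} (the Prunus S-RNase form).  A single
intron at position 5 is ambiguous between I-B and III-C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

from srscout.seq_io import AlignmentColumnMap, GeneStructure

DEFAULT_WINDOW = 7

_CANONICAL_PATTERNS: dict[str, tuple[str, frozenset[int]]] = {
    "I-A": ("I", frozenset({2})),
    "I-B": ("I", frozenset({5})),
    "I-C": ("I", frozenset({2, 5})),
    "I-D": ("I", frozenset({2, 5, 9})),
    "II": ("II", frozenset({3, 4, 5, 6, 7, 8, 10, 11})),
    "III-A": ("III", frozenset({5, 9})),
    "III-B*": ("III", frozenset({9})),
    "III-C": ("III", frozenset({5})),
    "III-D": ("III", frozenset({1, 5})),
}

PROVISIONAL_PATTERNS = frozenset({"III-B*"})


@dataclass
class IntronSite:
    """One intron of one gene: CDS offset, phase and alignment column."""

    gene_id: str
    cds_offset: int
    phase: int
    column: Optional[int] = None

    def __post_init__(self) -> None:
        if self.phase != self.cds_offset % 3:
            raise ValueError(
                f"{self.gene_id}: phase {self.phase} inconsistent with "
                f"offset {self.cds_offset}"
            )


@dataclass
class HomologousPosition:
    """A cluster of intron sites sharing one alignment position."""

    position_id: int
    member_sites: list[IntronSite]
    column_range: tuple[int, int]
    phase_conflict: bool = False

    @property
    def phases(self) -> set[int]:
        return {s.phase for s in self.member_sites}

    @property
    def phase(self) -> Optional[int]:
        ph = self.phases
        return next(iter(ph)) if len(ph) == 1 else None


@dataclass
class PatternCatalog:
    """Named intron presence patterns with their class context."""

    entries: dict[str, tuple[str, frozenset[int]]] = field(
        default_factory=lambda: dict(_CANONICAL_PATTERNS)
    )
    provisional: frozenset[str] = PROVISIONAL_PATTERNS

    def __post_init__(self) -> None:
        if len(self.entries) != len(set(self.entries)):
            raise ValueError("duplicate pattern names")

    def names_for(self, present: frozenset[int]) -> list[str]:
        return [name for name, (_cls, pos) in self.entries.items() if pos == present]

    def class_of(self, name: str) -> str:
        return self.entries[name][0]

    def positions_of(self, name: str) -> frozenset[int]:
        return self.entries[name][1]


DEFAULT_CATALOG = PatternCatalog()


def intron_sites(gene: GeneStructure, colmap: AlignmentColumnMap) -> list[IntronSite]:
    """One IntronSite per intron of ``gene``, anchored to the alignment.

    The anchor column is the column of the first coding nucleotide 3'
    of the intron (ungapped CDS position == the intron offset).
    """
    sites = []
    for off in gene.intron_offsets:
        if off not in colmap:
            raise ValueError(
                f"{gene.gene_id}: intron offset {off} outside the aligned row"
            )
        sites.append(
            IntronSite(
                gene_id=gene.gene_id,
                cds_offset=off,
                phase=off % 3,
                column=colmap[off],
            )
        )
    return sites


def cluster_positions(
    sites: Sequence[IntronSite], window: int = DEFAULT_WINDOW
) -> list[HomologousPosition]:
    """Single-linkage clustering of intron sites along alignment columns.

    Two sites link when both fit inside a ``window``-column window,
    i.e. |column difference| <= window - 1.  Clusters are labeled 1..k
    in ascending column order.  Phase conflicts within a cluster are
    flagged, never merged away.
    """
    if not sites:
        return []
    for s in sites:
        if s.column is None:
            raise ValueError(f"{s.gene_id}: site lacks an alignment column")
    ordered = sorted(sites, key=lambda s: (s.column, s.gene_id))
    clusters: list[list[IntronSite]] = [[ordered[0]]]
    for site in ordered[1:]:
        if site.column - clusters[-1][-1].column <= window - 1:
            clusters[-1].append(site)
        else:
            clusters.append([site])
    result = []
    for i, members in enumerate(clusters, start=1):
        cols = [s.column for s in members]
        result.append(
            HomologousPosition(
                position_id=i,
                member_sites=members,
                column_range=(min(cols), max(cols)),
                phase_conflict=len({s.phase for s in members}) > 1,
            )
        )
    return result


def load_reference_sites(path=None) -> dict[int, tuple[int, int]]:
    """Canonical position -> (reference column, phase) table."""
    if path is None:
        data = resources.files("srscout") / "data" / "reference_intron_sites.tsv"
        with resources.as_file(data) as p:
            return load_reference_sites(p)
    table = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pos, col, phase = line.split("\t")
            table[int(pos)] = (int(col), int(phase))
    return table


def label_canonical(
    clusters: Sequence[HomologousPosition],
    reference: Optional[Mapping[int, tuple[int, int]]] = None,
    window: int = DEFAULT_WINDOW,
) -> list[HomologousPosition]:
    """Relabel clusters with the canonical position ids 1..11.

    A cluster takes canonical id k when any member column lies within
    the seven-nucleotide window of position k's reference column; the
    nearest cluster wins on contention.  Unmatched clusters get novel
    labels starting at 12, in column order.
    """
    if reference is None:
        reference = load_reference_sites()
    taken: dict[int, tuple[int, HomologousPosition]] = {}
    unmatched: list[HomologousPosition] = []
    for cluster in clusters:
        best: Optional[tuple[int, int]] = None  # (distance, position)
        for pos, (col, _phase) in reference.items():
            dist = min(abs(c - col) for c in (cluster.column_range))
            if dist <= window - 1 and (best is None or dist < best[0]):
                best = (dist, pos)
        if best is None:
            unmatched.append(cluster)
            continue
        dist, pos = best
        if pos in taken and taken[pos][0] <= dist:
            unmatched.append(cluster)
        else:
            if pos in taken:
                unmatched.append(taken[pos][1])
            taken[pos] = (dist, cluster)
    for pos, (_dist, cluster) in taken.items():
        cluster.position_id = pos
    next_id = max(reference) + 1
    for cluster in sorted(unmatched, key=lambda c: c.column_range[0]):
        cluster.position_id = next_id
        next_id += 1
    return sorted(clusters, key=lambda c: c.position_id)


def presence_matrix(
    gene_spans: Mapping[str, Optional[tuple[int, int]]],
    positions: Sequence[HomologousPosition],
) -> pd.DataFrame:
    """Gene x position presence matrix with undetermined marks.

    ``gene_spans`` maps gene id to the (first, last) alignment column
    covered by its row, or None for records with no gene structure
    (e.g. cDNA).  Cell values: 1 intron present, 0 position spanned but
    intron absent, "U" position not spanned (undetermined).
    """
    cols = [p.position_id for p in positions]
    rows = {}
    for gene_id, span in gene_spans.items():
        row = []
        for pos in positions:
            members = {s.gene_id for s in pos.member_sites}
            if gene_id in members:
                row.append(1)
            elif span is None or not (
                span[0] <= pos.column_range[0] and pos.column_range[1] <= span[1]
            ):
                row.append("U")
            else:
                row.append(0)
        rows[gene_id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def assign_pattern(
    present: frozenset[int] | set[int], catalog: PatternCatalog = DEFAULT_CATALOG
) -> list[str]:
    """Name(s) of the catalog pattern(s) exactly matching ``present``.

    The empty set maps to ["no-intron"]; sets not in the catalog map to
    ["novel"].  A single intron at position 5 is genuinely ambiguous
    (I-B vs III-C) and returns both names.
    """
    present = frozenset(present)
    if not present:
        return ["no-intron"]
    names = catalog.names_for(present)
    return names if names else ["novel"]
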