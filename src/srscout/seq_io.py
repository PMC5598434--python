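"""Reading and writing the formats the toolkit touches.

Conventions enforced throughout the package:

* internal coordinates are 0-based, half-open;
* external GFF3-subset I/O is 1-based, inclusive (the GFF3 standard);
* an intron's insertion point is stored as the count of coding
  nucleotides 5' of it, which is strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files or records."""


@dataclass
class ProteinRecord:
    """An amino-acid sequence with optional signal-peptide boundary.

    ``signal_peptide_end`` is a 0-based exclusive index: residues
    ``seq[:signal_peptide_end]`` form the signal peptide and are excluded
    from pI calculations.  Ambiguity letters other than X are rejected.
    """

    id: str
    seq: str
    signal_peptide_end: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise FormatError(f"{self.id}: empty protein sequence")
        bad = set(self.seq) - PROTEIN_ALPHABET
        if bad:
            raise FormatError(
                f"{self.id}: ambiguous or non-amino-acid characters {sorted(bad)}"
            )
        if self.signal_peptide_end is not None and not (
            0 <= self.signal_peptide_end < len(self.seq)
        ):
            raise FormatError(
                f"{self.id}: signal_peptide_end {self.signal_peptide_end} "
                f"outside [0, {len(self.seq)})"
            )


@dataclass
class GeneStructure:
    """Ordered exon coordinates on a contig plus the derived CDS.

    ``exons`` are (start, end) pairs in 0-based half-open *contig*
    coordinates, sorted by start and non-overlapping.  ``intron_offsets``
    count coding nucleotides 5' of each intron along the transcript
    (5'->3'), so minus-strand genes are handled uniformly.  ``cds`` is
    the spliced transcript-strand sequence when the contig was supplied,
    else None.
    """

    gene_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: Optional[str] = None
    intron_offsets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise FormatError(f"{self.gene_id}: no exons")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise FormatError(f"{self.gene_id}: overlapping exons")
        for s, e in exons:
            if not (0 <= s < e):
                raise FormatError(f"{self.gene_id}: bad exon ({s}, {e})")
        self.exons = exons
        total = sum(e - s for s, e in exons)
        if not self.intron_offsets:
            self.intron_offsets = derive_intron_offsets(exons, self.strand)
        if len(self.intron_offsets) != len(exons) - 1:
            raise FormatError(
                f"{self.gene_id}: {len(self.intron_offsets)} intron offsets "
                f"for {len(exons)} exons"
            )
        for off in self.intron_offsets:
            if not (0 < off < total):
                raise FormatError(f"{self.gene_id}: intron offset {off} outside CDS")
        if self.cds is not None and len(self.cds) != total:
            raise FormatError(
                f"{self.gene_id}: CDS length {len(self.cds)} != exon total {total}"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (contig coordinates, half-open)."""
        return self.exons[0][0], self.exons[-1][1]


def derive_intron_offsets(exons: Sequence[tuple[int, int]], strand: str) -> list[int]:
    """Coding-nucleotide counts 5' of each intron, in transcript order."""
    lengths = [e - s for s, e in sorted(exons)]
    if strand == "-":
        lengths = lengths[::-1]
    offsets = []
    acc = 0
    for ln in lengths[:-1]:
        acc += ln
        offsets.append(acc)
    return offsets


@dataclass
class AlignmentColumnMap:
    """Map from ungapped sequence position to 0-based alignment column."""

    seq_id: str
    map: dict[int, int]

    def __getitem__(self, i: int) -> int:
        return self.map[i]

    def __contains__(self, i: int) -> bool:
        return i in self.map

    def __len__(self) -> int:
        return len(self.map)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercased sequence) pairs.

    Record ids are the first whitespace-delimited header token; file
    order is preserved.  Empty files and duplicate ids are errors.
    """
    records = []
    seen = set()
    with _open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate FASTA id: {rec.id!r}")
            seen.add(rec.id)
            records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Sequence[tuple[str, str]], width: int = 60) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def _open(path):
    return path if hasattr(path, "read") else open(path)


def column_map(seq_id: str, aligned_row: str, gap: str = "-") -> AlignmentColumnMap:
    """Map each ungapped position of one alignment row to its column."""
    mapping = {}
    i = 0
    for col, ch in enumerate(aligned_row):
        if ch != gap:
            mapping[i] = col
            i += 1
    return AlignmentColumnMap(seq_id=seq_id, map=mapping)


def gff_to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> GFF3 1-based inclusive."""
    return start + 1, end


def read_exon_table(
    path, contigs: Optional[Mapping[str, str]] = None
) -> list[GeneStructure]:
    """Read exon features from a GFF3-subset file into GeneStructures.

    Only ``exon`` features are consumed; the owning gene is taken from
    the ``Parent``, ``gene_id`` or ``ID`` attribute (first match).
    Coordinates are converted from GFF3 1-based inclusive to internal
    0-based half-open.  When ``contigs`` supplies sequences, the CDS is
    spliced (reverse-complemented for minus-strand genes) and exons are
    bounds-checked against the contig.
    """
    by_gene: dict[str, dict] = {}
    order: list[str] = []
    with _open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 tab-separated fields")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "exon":
                continue
            gene_id = _gene_id_from_attrs(attrs)
            if gene_id is None:
                raise FormatError(f"line {lineno}: exon lacks a gene identifier")
            s, e = gff_to_internal(int(start), int(end))
            entry = by_gene.setdefault(
                gene_id, {"contig": seqid, "strand": strand, "exons": []}
            )
            if gene_id not in order:
                order.append(gene_id)
            if entry["contig"] != seqid or entry["strand"] != strand:
                raise FormatError(f"{gene_id}: exons on mixed contigs or strands")
            entry["exons"].append((s, e))

    genes = []
    for gene_id in order:
        entry = by_gene[gene_id]
        exons = sorted(entry["exons"])
        contig_seq = contigs.get(entry["contig"]) if contigs else None
        cds = None
        if contig_seq is not None:
            for s, e in exons:
                if e > len(contig_seq):
                    raise FormatError(
                        f"{gene_id}: exon ({s}, {e}) outside contig "
                        f"{entry['contig']} (length {len(contig_seq)})"
                    )
            cds = splice_cds(contig_seq, exons, entry["strand"])
        genes.append(
            GeneStructure(
                gene_id=gene_id,
                contig_id=entry["contig"],
                strand=entry["strand"],
                exons=exons,
                cds=cds,
            )
        )
    return genes


def splice_cds(contig_seq: str, exons: Sequence[tuple[int, int]], strand: str) -> str:
    """Splice exon sequences into the transcript-strand CDS."""
    parts = [contig_seq[s:e].upper() for s, e in sorted(exons)]
    cds = "".join(parts)
    if strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _gene_id_from_attrs(attrs: str) -> Optional[str]:
    for part in attrs.rstrip(";").split(";"):
        part = part.strip()
        if "=" not in part:
            continue
        key, value = part.split("=", 1)
        if key in ("Parent", "gene_id", "ID"):
            return value
    return None
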