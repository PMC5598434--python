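"""Synthetic fixtures with known truth for every pipeline stage.

The generator emulates the statistical structure of the T2/S-RNase
family without any molecular-evolution realism: proteins are a fixed
~120-residue backbone of the five conserved-region exemplars joined by
class-specific linkers, charge-tuned to a target pI; genes insert
GT..AG introns at the canonical land-plant positions with the canonical
phases; haplotype contigs plant RNase genes and intact or
stop-disrupted F-box ORFs on random strands over an i.i.d. uniform
nucleotide background.

Defaults mirror the family-level observations the toolkit is built
around: class I and II panels acidic (pI ~ Normal(5.5, 0.8), truncated),
class III basic (Normal(8.8, 0.7)); class I dominated by pattern I-D,
class II invariantly the eight-intron pattern, class III dominated by
III-C; haplotypes with around half a dozen F-box loci, some carrying an
in-frame stop (the relict signature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from srscout import motifs as motifs_mod
from srscout.intron_arch import DEFAULT_CATALOG, PatternCatalog, load_reference_sites
from srscout.physchem import isoelectric_point
from srscout.seq_io import GeneStructure, ProteinRecord, splice_cds

REFERENCE_ALIGNMENT_LENGTH = 363  # 120 codons + stop, the reference CDS frame

_LINKER_LENGTHS = (12, 12, 12, 12, 12, 15)
_LINKER_ALPHABET = "ASTGLNQVIPFDEK"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# one deterministic codon per residue; no stop codons can arise in frame
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
    "X": "NNN",
}

_DEFAULT_PATTERN_WEIGHTS = {
    "I": {"I-D": 0.6, "I-C": 0.25, "I-A": 0.075, "I-B": 0.075},
    "II": {"II": 1.0},
    "III": {"III-C": 0.6, "III-D": 0.2, "III-A": 0.15, "III-B*": 0.05},
}
_DEFAULT_PI_TARGETS = {"I": (5.5, 0.8), "II": (5.5, 0.8), "III": (8.8, 0.7)}
_PI_TRUNCATION = (3.9, 9.9)


def _class_linkers(class_label: str) -> list[str]:
    """Fixed class-specific base linkers (deterministic per class)."""
    seed = {"I": 101, "II": 202, "III": 303}[class_label]
    rng = np.random.default_rng(seed)
    return [
        "".join(rng.choice(list(_LINKER_ALPHABET), size=n))
        for n in _LINKER_LENGTHS
    ]


def backtranslate(protein: str) -> str:
    """Fixed-codon back-translation (deterministic)."""
    return "".join(_CODON[aa] for aa in protein)


def make_protein(
    class_label: str,
    pI_target: float,
    seed: int,
    panel: Optional[Sequence[motifs_mod.MotifProfile]] = None,
    record_id: Optional[str] = None,
    pi_tol: float = 0.3,
    max_swaps: int = 500,
) -> ProteinRecord:
    """Build a synthetic protein of the given class near a target pI.

    The backbone concatenates one exemplar window per conserved region
    (so all five regions hit at score 1.0) with class-specific linkers;
    charged residues are then swapped into or out of linker positions
    until the Bjellqvist pI is within ``pi_tol`` of the target.
    Deterministic per (class_label, pI_target, seed).
    """
    if not (3.0 < pI_target < 12.0):
        raise ValueError(f"pI target {pI_target} outside (3, 12)")
    if panel is None:
        panel = motifs_mod.default_motif_panel()
    rng = np.random.default_rng(seed)
    linkers = list(_class_linkers(class_label))
    # individual variation: mutate linker residues at a low rate
    for i, linker in enumerate(linkers):
        chars = list(linker)
        for j in range(len(chars)):
            if rng.random() < 0.15:
                chars[j] = str(rng.choice(list(_LINKER_ALPHABET)))
        linkers[i] = "".join(chars)

    exemplars = [str(rng.choice(p.exemplar_windows)) for p in panel]
    parts = []
    linker_spans = []
    pos = 0
    for i, ex in enumerate(exemplars):
        parts.append(linkers[i])
        linker_spans.append((pos, pos + len(linkers[i])))
        pos += len(linkers[i])
        parts.append(ex)
        pos += len(ex)
    parts.append(linkers[-1])
    linker_spans.append((pos, pos + len(linkers[-1])))
    seq = list("".join(parts))
    linker_positions = [i for s, e in linker_spans for i in range(s, e)]

    # hill-climb on |pI - target| over single linker mutations; histidine
    # provides fine charge steps where the titration curve is flat
    swap_residues = "KRDEHASTG"
    diff = abs(isoelectric_point("".join(seq)) - pI_target)
    for _ in range(max_swaps):
        if diff <= pi_tol:
            break
        best_move = None
        for _c in range(30):
            i = int(rng.choice(linker_positions))
            aa = str(rng.choice(list(swap_residues)))
            if seq[i] == aa:
                continue
            old = seq[i]
            seq[i] = aa
            d = abs(isoelectric_point("".join(seq)) - pI_target)
            seq[i] = old
            if best_move is None or d < best_move[0]:
                best_move = (d, i, aa)
        if best_move is None or best_move[0] >= diff:
            continue
        diff, i, aa = best_move
        seq[i] = aa
    else:
        raise ValueError(f"could not reach pI {pI_target} within {max_swaps} swaps")
    return ProteinRecord(
        id=record_id or f"{class_label}_pi{pI_target:.1f}_s{seed}",
        seq="".join(seq),
        source=f"synthetic class {class_label}",
    )


def make_gene(
    protein: ProteinRecord,
    pattern_name: str,
    seed: int,
    catalog: PatternCatalog = DEFAULT_CATALOG,
    contig_flank: int = 200,
    strand: Optional[str] = None,
) -> tuple[GeneStructure, str, str]:
    """Realize a protein as a gene structure with a named intron pattern.

    Back-translates the protein (plus a TAA stop), inserts GT..AG
    introns at the canonical CDS offsets of the pattern's positions
    (with a +/-1 codon phase-preserving jitter), and returns the gene
    structure, its contig fragment, and the gapped alignment row in the
    bundled reference column frame.
    """
    rng = np.random.default_rng(seed)
    cds = backtranslate(protein.seq) + "TAA"
    reference = load_reference_sites()
    if pattern_name == "no-intron":
        positions: list[int] = []
    else:
        positions = sorted(catalog.positions_of(pattern_name))
    offsets = []
    for pos in positions:
        col, _phase = reference[pos]
        off = col + 3 * int(rng.integers(-1, 2))
        if not (0 < off < len(cds)):
            raise ValueError(
                f"position {pos} (offset {off}) beyond CDS length {len(cds)}"
            )
        offsets.append(off)

    pieces = []
    prev = 0
    intron_lengths = []
    for off in offsets:
        pieces.append(cds[prev:off])
        ilen = int(rng.integers(60, 181))
        intron_lengths.append(ilen)
        prev = off
    pieces.append(cds[prev:])

    flank5 = _random_nt(rng, contig_flank)
    flank3 = _random_nt(rng, contig_flank)
    contig_parts = [flank5]
    exons_plus = []
    cursor = len(flank5)
    for i, piece in enumerate(pieces):
        exons_plus.append((cursor, cursor + len(piece)))
        contig_parts.append(piece)
        cursor += len(piece)
        if i < len(intron_lengths):
            intron = "GT" + _random_nt(rng, intron_lengths[i] - 4) + "AG"
            contig_parts.append(intron)
            cursor += len(intron)
    contig_parts.append(flank3)
    contig = "".join(contig_parts)

    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        length = len(contig)
        contig = str(Seq(contig).reverse_complement())
        exons = sorted((length - e, length - s) for s, e in exons_plus)
    else:
        exons = exons_plus

    gene = GeneStructure(
        gene_id=protein.id,
        contig_id=f"{protein.id}_contig",
        strand=strand,
        exons=exons,
        cds=splice_cds(contig, exons, strand),
    )
    if len(cds) > REFERENCE_ALIGNMENT_LENGTH:
        raise ValueError("CDS exceeds the reference alignment frame")
    aligned_row = cds + "-" * (REFERENCE_ALIGNMENT_LENGTH - len(cds))
    return gene, contig, aligned_row


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n > 0 else ""


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset or haplotype."""

    seed: int = 0
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"I": 10, "II": 10, "III": 10}
    )
    pI_targets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_PI_TARGETS)
    )
    intron_patterns: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            c: dict(w) for c, w in _DEFAULT_PATTERN_WEIGHTS.items()
        }
    )
    n_class3_rnase: int = 1
    n_fbox_intact: int = 6
    n_fbox_disrupted: int = 2
    fbox_distance_range: Optional[tuple[int, int]] = None
    # F-box-homologous ORFs planted at lengths outside [900, 1800] nt to
    # probe the scanner's length bounds (never counted toward candidacy)
    fbox_out_of_bounds_lengths: tuple[int, ...] = ()
    contig_length: int = 2_000_000
    n_gap_runs: int = 0

    def __post_init__(self) -> None:
        for n in (
            *self.n_per_class.values(),
            self.n_class3_rnase,
            self.n_fbox_intact,
            self.n_fbox_disrupted,
            self.n_gap_runs,
        ):
            if n < 0:
                raise ValueError("fixture counts must be >= 0")


@dataclass
class TruthTable:
    """Planted truth for one haplotype contig."""

    contig_id: str
    rnase_loci: list[tuple[tuple[int, int], str]] = field(default_factory=list)
    intact_fbox: list[tuple[int, int, str]] = field(default_factory=list)
    disrupted_fbox: list[tuple[int, int, str]] = field(default_factory=list)
    out_of_bounds_fbox: list[tuple[int, int, str]] = field(default_factory=list)
    candidate: bool = False

    def validate(self, contig: str) -> None:
        """Check planted coordinates against the emitted contig."""
        for start, end, strand in self.intact_fbox:
            seq = contig[start:end]
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
            if not seq.startswith("ATG") or seq[-3:] not in ("TAA", "TAG", "TGA"):
                raise AssertionError(f"intact F-box at {(start, end)} malformed")
            internal = str(Seq(seq[:-3]).translate())
            if "*" in internal:
                raise AssertionError(
                    f"intact F-box at {(start, end)} has an internal stop"
                )
        for start, end, strand in self.disrupted_fbox:
            seq = contig[start:end]
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
            if "*" not in str(Seq(seq[:-3]).translate()):
                raise AssertionError(
                    f"disrupted F-box at {(start, end)} lacks an internal stop"
                )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds=_PI_TRUNCATION
) -> float:
    for _ in range(1000):
        x = float(rng.normal(mean, sd))
        if bounds[0] <= x <= bounds[1]:
            return x
    raise RuntimeError("truncated normal failed to sample within bounds")


def make_classified_panel(
    spec: FixtureSpec,
    catalog: PatternCatalog = DEFAULT_CATALOG,
) -> list[dict]:
    """Generate labeled records with genes and aligned rows.

    Returns one dict per record: id, true_class, true_pattern, protein,
    gene, contig, aligned_row, pI_target.  Pattern names are drawn from
    the class-specific catalog weights; pI targets from the class
    truncated normals.
    """
    rng = np.random.default_rng(spec.seed)
    panel = motifs_mod.default_motif_panel()
    records = []
    for class_label in ("I", "II", "III"):
        n = spec.n_per_class.get(class_label, 0)
        weights = spec.intron_patterns[class_label]
        names = list(weights)
        probs = np.array([weights[n_] for n_ in names], dtype=float)
        probs /= probs.sum()
        mean, sd = spec.pI_targets[class_label]
        for i in range(n):
            target = _truncated_normal(rng, mean, sd)
            sub = int(rng.integers(2**31))
            protein = make_protein(
                class_label,
                target,
                seed=sub,
                panel=panel,
                record_id=f"{class_label}_{i:03d}",
            )
            pattern = str(rng.choice(names, p=probs))
            gene, contig, row = make_gene(
                protein, pattern, seed=int(rng.integers(2**31)), catalog=catalog
            )
            records.append(
                {
                    "id": protein.id,
                    "true_class": class_label,
                    "true_pattern": pattern,
                    "pI_target": target,
                    "protein": protein,
                    "gene": gene,
                    "contig": contig,
                    "aligned_row": row,
                }
            )
    return records


# planted features keep this much clearance so sliding windows never
# bridge two features
_FEATURE_SPACING = 2000


def _clear(start: int, end: int, occupied: list[tuple[int, int]]) -> bool:
    return all(
        not (s - _FEATURE_SPACING < end and start < e + _FEATURE_SPACING)
        for s, e in occupied
    )


def _plant(
    background: list[str], start: int, fragment: str, occupied: list[tuple[int, int]]
) -> None:
    end = start + len(fragment)
    if not _clear(start, end, occupied):
        raise ValueError("feature placement overlaps an existing feature")
    background[start:end] = list(fragment)
    occupied.append((start, end))


def _make_fbox_cds(
    rng: np.random.Generator,
    refs: Sequence[tuple[str, str]],
    disrupted: bool,
) -> str:
    """A planted F-box coding sequence (sense codons, ATG..stop)."""
    if disrupted:
        eligible = [r for _id, r in refs if len(r) >= 334]
        ref = eligible[int(rng.integers(len(eligible)))]
        n_aa = int(rng.integers(333, min(len(ref), 499) + 1))
    else:
        ref = refs[int(rng.integers(len(refs)))][1]
        n_aa = int(rng.integers(299, min(len(ref), 599) + 1))
    protein = list("M" + ref[1:n_aa])
    for j in range(1, len(protein)):
        if rng.random() < 0.03:
            protein[j] = str(rng.choice(list(_AA20)))
    cds = backtranslate("".join(protein))
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    if disrupted:
        # internal stop placed so neither flanking ORF reaches 900 nt
        c = n_aa - 250
        cds = cds[: 3 * c] + "TGA" + cds[3 * (c + 1) :]
    return cds + stop


def make_haplotype(
    spec: FixtureSpec,
    fbox_refs: Optional[Sequence[tuple[str, str]]] = None,
    contig_id: str = "synthetic_haplotype",
    flank_nt: int = 2_000_000,
    min_fbox: int = 4,
) -> tuple[str, TruthTable]:
    """Plant RNase gene(s) and F-box ORFs on a random background contig.

    Features go on random strands at random non-overlapping offsets
    (or, when ``fbox_distance_range`` is set, at controlled distances
    from the first RNase locus).  The truth table records every planted
    feature and the expected candidacy verdict under the default flank
    and ``min_fbox`` rules.
    """
    from srscout.slocus_scan import load_fbox_refs

    rng = np.random.default_rng(spec.seed)
    if fbox_refs is None:
        fbox_refs = load_fbox_refs()
    background = list(_random_nt(rng, spec.contig_length))
    occupied: list[tuple[int, int]] = []
    truth = TruthTable(contig_id=contig_id)

    margin = 2000

    def random_start(frag_len: int) -> int:
        for _ in range(200):
            start = int(rng.integers(margin, spec.contig_length - frag_len - margin))
            if _clear(start, start + frag_len, occupied):
                return start
        raise ValueError("contig capacity overflow while placing features")

    # RNase loci (class III, single-intron III-C structure); when F-box
    # distances are controlled the anchor locus sits near the contig start
    for i in range(spec.n_class3_rnase):
        protein = make_protein(
            "III", 9.0, seed=int(rng.integers(2**31)), record_id=f"rnase_{i}"
        )
        _gene, fragment, _row = make_gene(
            protein, "III-C", seed=int(rng.integers(2**31))
        )
        if spec.fbox_distance_range is not None and i == 0:
            start = int(rng.integers(margin, margin + 20_000))
        else:
            start = random_start(len(fragment))
        _plant(background, start, fragment, occupied)
        truth.rnase_loci.append(((start, start + len(fragment)), "III"))

    anchor = truth.rnase_loci[0][0] if truth.rnase_loci else (0, 0)

    def fbox_start(frag_len: int) -> int:
        if spec.fbox_distance_range is None:
            return random_start(frag_len)
        lo, hi = spec.fbox_distance_range
        for _ in range(200):
            start = anchor[1] + int(rng.integers(lo, hi))
            if start + frag_len + margin > spec.contig_length:
                raise ValueError("fbox_distance_range exceeds contig capacity")
            if _clear(start, start + frag_len, occupied):
                return start
        raise ValueError("contig capacity overflow while placing features")

    for kind, count in (("intact", spec.n_fbox_intact), ("disrupted", spec.n_fbox_disrupted)):
        for _ in range(count):
            cds = _make_fbox_cds(rng, fbox_refs, disrupted=(kind == "disrupted"))
            strand = "+" if rng.random() < 0.5 else "-"
            fragment = cds if strand == "+" else str(Seq(cds).reverse_complement())
            start = fbox_start(len(fragment))
            _plant(background, start, fragment, occupied)
            record = (start, start + len(fragment), strand)
            if kind == "intact":
                truth.intact_fbox.append(record)
            else:
                truth.disrupted_fbox.append(record)

    # stops in all three frames: blocks upstream ATG read-through into a
    # planted out-of-bounds feature
    barrier = "TAAATAAATAAA"
    for nt_length in spec.fbox_out_of_bounds_lengths:
        if nt_length % 3:
            raise ValueError("out-of-bounds F-box lengths must be codon multiples")
        n_aa = nt_length // 3 - 1
        ref = max((r for _id, r in fbox_refs), key=len)
        tiled = (ref * (n_aa // len(ref) + 1))[:n_aa]
        protein = ("M" + tiled[1:]).replace("M", "L")
        protein = "M" + protein[1:]
        cds = backtranslate(protein) + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = barrier + cds
        if strand == "-":
            fragment = str(Seq(fragment).reverse_complement())
        start = fbox_start(len(fragment))
        _plant(background, start, fragment, occupied)
        if strand == "+":
            feature = (start + len(barrier), start + len(fragment), "+")
        else:
            feature = (start, start + len(fragment) - len(barrier), "-")
        truth.out_of_bounds_fbox.append(feature)

    for _ in range(spec.n_gap_runs):
        run = "N" * int(rng.integers(N_GAP_MIN, N_GAP_MAX))
        start = random_start(len(run))
        _plant(background, start, run, occupied)

    contig = "".join(background)

    def within_flank(feat: tuple[int, int, str]) -> bool:
        return any(
            feat[0] >= s - flank_nt and feat[1] <= e + flank_nt
            for (s, e), _cls in truth.rnase_loci
        )

    n_in_flank = sum(
        1 for feat in truth.intact_fbox + truth.disrupted_fbox if within_flank(feat)
    )
    truth.candidate = bool(truth.rnase_loci) and n_in_flank >= min_fbox
    return contig, truth


N_GAP_MIN = 12
N_GAP_MAX = 40
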