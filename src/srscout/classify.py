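"""Class I/II/III assignment and S-RNase candidate calling.

Three lines of evidence feed the call:

* the intron presence pattern, matched against the canonical catalog
  (most patterns are class-specific; a single intron at position 5 is
  ambiguous between I-B and III-C);
* the isoelectric point — classes I and II are typically acidic,
  class III basic, and functional S-RNases rarely show pI < 8.0;
* similarity to a labeled exemplar panel (nearest-reference by global
  alignment distance), a deterministic stand-in for phylogenetic
  placement.

The decision ladder: a uniquely class-matching intron pattern decides
alone (confidence "pattern-exact"); otherwise the pI side (acidic =>
I/II, basic => III at 7.0) and the nearest-reference label vote, with
confidence "multi-line" when at least two lines agree and "single-line"
otherwise.  The S-RNase candidate flag requires class III, pI >= 8.0, an
S-RNase-compatible intron pattern (III-C, III-D, or undetermined — but
never III-A, since known S-RNases lack position 9), an intact CAS II
histidine, and at least three conserved regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from srscout import intron_arch, motifs, physchem
from srscout.intron_arch import DEFAULT_CATALOG, PatternCatalog
from srscout.seq_io import NUCLEOTIDE_ALPHABET, GeneStructure, column_map, read_fasta

BLOSUM62 = substitution_matrices.load("BLOSUM62")

CLASSES = ("I", "II", "III")


@dataclass
class Thresholds:
    """Tunable cutoffs of the decision ladder."""

    pi_basic: float = 7.0  # acidic/basic vote boundary
    pi_candidate: float = 8.0  # functional S-RNases rarely sit below this
    nn_max_distance: float = 0.95  # beyond this the panel is uninformative
    nn_k: int = 3


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class FeatureVector:
    """Per-sequence evidence bundle feeding classification."""

    id: str
    pI: float
    regions_hit: int
    cas2_his: Optional[bool] = None
    intron_pattern: Optional[frozenset[int]] = None
    pattern_names: list[str] = field(default_factory=list)
    nn_class: Optional[tuple[str, float]] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.pI < 14.0):
            raise ValueError(f"{self.id}: pI {self.pI} outside (0, 14)")
        if not (0 <= self.regions_hit <= 5):
            raise ValueError(f"{self.id}: regions_hit must be 0..5")


@dataclass
class ClassCall:
    """Classification verdict with its supporting evidence."""

    class_label: str
    s_rnase_candidate: bool
    evidence: list[tuple[str, str]]
    confidence: str

    def __post_init__(self) -> None:
        if self.s_rnase_candidate and self.class_label != "III":
            raise ValueError("S-RNase candidates must be class III")


def global_align_score(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> float:
    """Needleman–Wunsch global alignment score with affine gaps.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    ``matrix`` is a substitution matrix (default BLOSUM62) or a
    (match, mismatch) pair.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if matrix is None:
        matrix = BLOSUM62
    if isinstance(matrix, tuple):
        aligner.match_score, aligner.mismatch_score = matrix
    else:
        aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return float(aligner.score(a, b))


def alignment_distance(a: str, b: str, **kwargs) -> float:
    """Normalized alignment distance d = 1 - S(a,b)/min(S(a,a), S(b,b))."""
    self_a = global_align_score(a, a, **kwargs)
    self_b = global_align_score(b, b, **kwargs)
    return 1.0 - global_align_score(a, b, **kwargs) / min(self_a, self_b)


def nearest_reference(
    protein: str,
    refs: Sequence[tuple[str, str, str]],
    k: int = 3,
    max_distance: float = 0.95,
    **align_kwargs,
) -> tuple[str, float]:
    """Label a query by its k nearest labeled exemplars.

    ``refs`` are (id, sequence, class-label) triples.  The label is the
    majority class among the k nearest by ``alignment_distance``; label
    ties fall to the smaller mean distance, then to "unclassified".
    When every exemplar is at distance >= ``max_distance`` the panel is
    uninformative and the query is "unclassified".
    """
    if not refs:
        raise ValueError("empty reference panel")
    dists = sorted(
        ((alignment_distance(protein, seq, **align_kwargs), label, rid)
         for rid, seq, label in refs),
        key=lambda t: (t[0], t[2]),
    )
    if dists[0][0] >= max_distance:
        return "unclassified", dists[0][0]
    top = dists[: min(k, len(dists))]
    by_label: dict[str, list[float]] = {}
    for d, label, _rid in top:
        by_label.setdefault(label, []).append(d)
    best_count = max(len(v) for v in by_label.values())
    tied = [lab for lab, v in by_label.items() if len(v) == best_count]
    if len(tied) == 1:
        winner = tied[0]
    else:
        means = {lab: sum(by_label[lab]) / len(by_label[lab]) for lab in tied}
        low = min(means.values())
        lowest = [lab for lab in tied if means[lab] == low]
        if len(lowest) != 1:
            return "unclassified", dists[0][0]
        winner = lowest[0]
    return winner, min(by_label[winner])


def classify_sequence(
    fv: FeatureVector,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    catalog: PatternCatalog = DEFAULT_CATALOG,
) -> ClassCall:
    """Apply the decision ladder to one feature vector."""
    evidence: list[tuple[str, str]] = []

    pattern_classes: Optional[set[str]] = None
    names = [n for n in fv.pattern_names if n in catalog.entries]
    if fv.intron_pattern is not None and names:
        pattern_classes = {catalog.class_of(n) for n in names}
        evidence.append(("intron-pattern", "/".join(sorted(names))))
    elif fv.intron_pattern is None:
        evidence.append(("intron-pattern", "undetermined"))
    else:
        evidence.append(("intron-pattern", fv.pattern_names[0] if fv.pattern_names else "novel"))

    pi_side = {"III"} if fv.pI >= thresholds.pi_basic else {"I", "II"}
    evidence.append(("pI", f"{fv.pI:.2f} ({'basic' if fv.pI >= thresholds.pi_basic else 'acidic'})"))

    nn_label: Optional[str] = None
    if fv.nn_class is not None and fv.nn_class[0] in CLASSES:
        nn_label = fv.nn_class[0]
        evidence.append(("nearest-reference", f"{nn_label} (d={fv.nn_class[1]:.3f})"))

    if pattern_classes is not None and len(pattern_classes) == 1:
        label = next(iter(pattern_classes))
        confidence = "pattern-exact"
    else:
        support: dict[str, int] = {c: 0 for c in CLASSES}
        for c in CLASSES:
            if pattern_classes is not None and c in pattern_classes:
                support[c] += 1
            if c in pi_side:
                support[c] += 1
            if nn_label == c:
                support[c] += 1
        best = max(support.values())
        winners = [c for c in CLASSES if support[c] == best]
        if len(winners) == 1:
            label = winners[0]
        elif nn_label in winners:
            label = nn_label
        else:
            label = "unclassified"
        confidence = "multi-line" if label != "unclassified" and best >= 2 else "single-line"
        if label == "unclassified":
            confidence = "single-line"

    candidate = _s_rnase_candidate(fv, label, thresholds)
    evidence.append(("s-rnase-candidate", str(candidate)))
    return ClassCall(
        class_label=label,
        s_rnase_candidate=candidate,
        evidence=evidence,
        confidence=confidence,
    )


def _s_rnase_candidate(fv: FeatureVector, label: str, thresholds: Thresholds) -> bool:
    if label != "III":
        return False
    if fv.pI < thresholds.pi_candidate:
        return False
    if fv.cas2_his is False:
        return False
    if fv.regions_hit < 3:
        return False
    if fv.intron_pattern is None:
        return True  # cDNA input: pattern unknown, weaker confidence
    return bool({"III-C", "III-D"} & set(fv.pattern_names))


def _is_nucleotide(seq: str) -> bool:
    return bool(seq) and set(seq) <= NUCLEOTIDE_ALPHABET


_STOPS = {"TAA", "TAG", "TGA"}


def _longest_orf_protein(seq: str) -> Optional[str]:
    """Translate the longest ATG..stop ORF found on either strand."""
    best = ""
    for strand_seq in (seq, str(Seq(seq).reverse_complement())):
        for frame in range(3):
            codons = [
                strand_seq[i : i + 3]
                for i in range(frame, len(strand_seq) - 2, 3)
            ]
            start = None
            for idx, codon in enumerate(codons):
                if start is None and codon == "ATG":
                    start = idx
                elif start is not None and codon in _STOPS:
                    orf = "".join(codons[start:idx])
                    if len(orf) > len(best):
                        best = orf
                    start = None
    if not best:
        return None
    return str(Seq(best).translate())


def classify_fasta(
    seqs: Sequence[tuple[str, str]],
    genes: Optional[Mapping[str, GeneStructure]] = None,
    alignment: Optional[Mapping[str, str]] = None,
    refs: Optional[Sequence[tuple[str, str, str]]] = None,
    panel: Optional[Sequence[motifs.MotifProfile]] = None,
    catalog: PatternCatalog = DEFAULT_CATALOG,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    signal_peptides: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Run the full pipeline over a batch of sequences.

    Nucleotide inputs are translated after longest-ORF extraction.
    Records with a gene structure and an aligned CDS row get intron
    evidence; others are classified with the pattern undetermined.
    Untranslatable nucleotide records produce an error row, and the run
    continues.  Returns one row per input sequence.
    """
    if panel is None:
        panel = motifs.default_motif_panel()
    genes = genes or {}
    alignment = alignment or {}
    signal_peptides = signal_peptides or {}

    # intron evidence is computed jointly across all structured records
    patterns: dict[str, frozenset[int]] = {}
    structured = [gid for gid in genes if gid in alignment]
    if structured:
        all_sites = []
        spans: dict[str, Optional[tuple[int, int]]] = {}
        for gid in structured:
            cmap = column_map(gid, alignment[gid])
            all_sites.extend(intron_arch.intron_sites(genes[gid], cmap))
            cols = sorted(cmap.map.values())
            spans[gid] = (cols[0], cols[-1]) if cols else None
        clusters = intron_arch.label_canonical(intron_arch.cluster_positions(all_sites))
        for gid in structured:
            present = frozenset(
                p.position_id
                for p in clusters
                if gid in {s.gene_id for s in p.member_sites}
            )
            patterns[gid] = present

    rows = []
    for rec_id, seq in seqs:
        seq = seq.upper()
        try:
            if _is_nucleotide(seq):
                protein = _longest_orf_protein(seq)
                if protein is None:
                    raise ValueError("no open reading frame found")
                cds_length = 3 * len(protein) + 3
            else:
                protein = seq
                cds_length = 3 * len(protein)
            spe = signal_peptides.get(rec_id)
            mature = protein[spe:] if spe else protein
            if not mature:
                raise ValueError("signal peptide boundary leaves no mature chain")
            hits = motifs.scan_conserved_regions(mature, panel)
            status = motifs.catalytic_histidines(hits, panel)
            pi = physchem.isoelectric_point(mature)
            present = patterns.get(rec_id)
            names = (
                intron_arch.assign_pattern(present, catalog)
                if present is not None
                else []
            )
            nn = None
            if refs:
                nn = nearest_reference(
                    mature, refs, k=thresholds.nn_k,
                    max_distance=thresholds.nn_max_distance,
                )
            fv = FeatureVector(
                id=rec_id,
                pI=pi,
                regions_hit=len({h.region_id for h in hits}),
                cas2_his=status.cas2_his,
                intron_pattern=present,
                pattern_names=names,
                nn_class=nn,
            )
            call = classify_sequence(fv, thresholds, catalog)
            rows.append(
                {
                    "id": rec_id,
                    "class": call.class_label,
                    "confidence": call.confidence,
                    "pI": round(pi, 2),
                    "pattern": "/".join(names) if names else "undetermined",
                    "regions_hit": fv.regions_hit,
                    "cas2": _tristate(status.cas2_his),
                    "candidate": call.s_rnase_candidate,
                    "passes_filter": motifs.passes_inclusion_filter(cds_length, hits),
                    "evidence": "; ".join(f"{k}={v}" for k, v in call.evidence),
                }
            )
        except ValueError as exc:
            rows.append(
                {
                    "id": rec_id,
                    "class": "error",
                    "confidence": "",
                    "pI": float("nan"),
                    "pattern": "",
                    "regions_hit": 0,
                    "cas2": "",
                    "candidate": False,
                    "passes_filter": False,
                    "evidence": str(exc),
                }
            )
    columns = [
        "id", "class", "confidence", "pI", "pattern", "regions_hit",
        "cas2", "candidate", "passes_filter", "evidence",
    ]
    return pd.DataFrame(rows, columns=columns)


def _tristate(value: Optional[bool]) -> str:
    if value is None:
        return "undetermined"
    return "present" if value else "absent"


def load_reference_panel(fasta_path, labels_path) -> list[tuple[str, str, str]]:
    """Load a labeled exemplar panel: FASTA plus (id, class) TSV."""
    labels = {}
    with open(labels_path) if not hasattr(labels_path, "read") else labels_path as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, label = line.split("\t")
            labels[rid] = label
    panel = []
    for rid, seq in read_fasta(fasta_path):
        if rid not in labels:
            raise ValueError(f"reference {rid} has no class label")
        panel.append((rid, seq, labels[rid]))
    return panel


def default_reference_panel() -> list[tuple[str, str, str]]:
    """The bundled synthetic class exemplar panel."""
    data = resources.files("srscout") / "data"
    with resources.as_file(
        data / "synthetic_class_exemplars.fasta"
    ) as fasta_path, resources.as_file(
        data / "synthetic_class_exemplars.tsv"
    ) as labels_path:
        return load_reference_panel(fasta_path, labels_path)
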