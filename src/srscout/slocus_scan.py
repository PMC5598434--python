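"""Scanning genome contigs for putative (possibly relict) S-loci.

An S-locus couples a pistil-expressed class III T2/S-RNase with several
tightly linked pollen-expressed F-box genes (SLF/SFB).  The scanner
looks for that signature around supplied RNase loci:

* intact F-box candidates are ATG..stop open reading frames between
  900 bp and 1.8 kb (stop included) on either strand whose translation
  scores against an F-box exemplar panel;
* relict (pseudogenized) F-box copies are found by sliding translated
  windows through stop codons and flagging high-scoring windows that
  contain an in-frame stop — the decay signature of relict haplotypes;
* a haplotype is an S-locus candidate when at least ``min_fbox`` F-box
  loci (intact or disrupted) lie within the 2 Mb flank of a class III
  RNase locus.  Class I/II RNases with many neighboring F-boxes are
  reported but never candidates.

Assembly gaps (runs of >= 10 N) break ORFs and windows; isolated N
bases translate to X and do not terminate an ORF.
"""

from __future__ import annotations

import math
import re
from bisect import bisect_left
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from Bio.Seq import Seq

from srscout.classify import global_align_score
from srscout.seq_io import read_fasta

DEFAULT_MIN_ORF_NT = 900
DEFAULT_MAX_ORF_NT = 1800
DEFAULT_FLANK_NT = 2_000_000
DEFAULT_MIN_FBOX = 4
DEFAULT_FBOX_TAU = 0.25
DEFAULT_WINDOW_NT = 1200
DEFAULT_STEP_NT = 300
N_BREAK_RUN = 10
_SEED_K = 5  # shared-peptide seed length for the sliding-window screen
_MIN_SEEDS = 2
# a stop is "disruptive" only with this much seed support within this
# many codons on each side — homology interrupted by the stop
_FLANK_AA = 50
_MIN_FLANK_SEEDS = 3

_STOP_RE = re.compile(r"(?=(TAA|TAG|TGA))")
_ATG_RE = re.compile(r"(?=(ATG))")
_N_RUN_RE = re.compile(r"N{%d,}" % N_BREAK_RUN)


@dataclass
class OrfHit:
    """One F-box candidate locus (intact ORF or disrupted region)."""

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    nt_length: int
    protein: str
    fbox_score: float = math.nan
    disrupted: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start != self.nt_length:
            raise ValueError("nt_length inconsistent with coordinates")
        if self.disrupted:
            if self.nt_length < 300:
                raise ValueError("disrupted hits must span >= 300 nt")
        # intact hits obey the ORF length bounds at construction sites


@dataclass
class HaplotypeReport:
    """Fig-style summary of one genomic window around RNase loci."""

    contig_id: str
    rnase_loci: list[tuple[tuple[int, int], str]]
    fbox_loci: list[OrfHit]
    candidate: bool
    min_fbox: int
    notes: list[str] = field(default_factory=list)

    def features(self) -> list[tuple[int, int, str, str, bool]]:
        """(start, end, kind, strand, disrupted) sorted by coordinate."""
        feats = [
            (s, e, f"RNase-{cls}", ".", False) for (s, e), cls in self.rnase_loci
        ]
        feats += [
            (h.start, h.end, "F-box", h.strand, h.disrupted) for h in self.fbox_loci
        ]
        return sorted(feats)

    def to_rows(self) -> list[dict]:
        """Report rows with distances (kb) between consecutive features."""
        rows = []
        prev_end: Optional[int] = None
        for start, end, kind, strand, disrupted in self.features():
            dist_kb = None if prev_end is None else max(0, start - prev_end) / 1000.0
            rows.append(
                {
                    "contig": self.contig_id,
                    "type": kind,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "disrupted": disrupted,
                    "distance_to_previous_kb": dist_kb,
                }
            )
            prev_end = end
        return rows


def _n_runs(seq: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in _N_RUN_RE.finditer(seq)]


def _overlaps_any(start: int, end: int, runs: list[tuple[int, int]]) -> bool:
    for s, e in runs:
        if s < end and start < e:
            return True
    return False


def _orfs_one_strand(
    seq: str, min_nt: int, max_nt: int, require_atg: bool, include_stop: bool
) -> list[tuple[int, int]]:
    """(start, end) of every qualifying ORF on the given strand sequence."""
    stops = [m.start(1) for m in _STOP_RE.finditer(seq)]
    stops_by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for p in stops:
        stops_by_frame[p % 3].append(p)
    runs = _n_runs(seq)
    if require_atg:
        starts = [m.start(1) for m in _ATG_RE.finditer(seq)]
    else:
        starts = []
        for f in range(3):
            prev = f
            for q in stops_by_frame[f]:
                starts.append(prev)
                prev = q + 3
    found = []
    for p in starts:
        frame_stops = stops_by_frame[p % 3]
        i = bisect_left(frame_stops, p + 3)
        if i == len(frame_stops):
            continue
        q = frame_stops[i]
        end = q + 3
        length = (end - p) if include_stop else (q - p)
        if not (min_nt <= length <= max_nt):
            continue
        if _overlaps_any(p, end, runs):
            continue
        found.append((p, end))
    return found


def find_orfs(
    contig: str,
    min_nt: int = DEFAULT_MIN_ORF_NT,
    max_nt: int = DEFAULT_MAX_ORF_NT,
    contig_id: str = "",
    require_atg: bool = True,
    include_stop: bool = True,
    longest_per_stop: bool = False,
) -> list[OrfHit]:
    """Six-frame ORF scan: every ATG walked to its next in-frame stop.

    Length bounds are inclusive and, by default, count the stop codon.
    Codons containing N translate to X and do not terminate the walk;
    runs of >= 10 N (assembly gaps) break ORFs.  With
    ``longest_per_stop`` only the longest in-bounds ORF per (strand,
    stop codon) is kept — one locus, one hit.
    """
    contig = contig.upper()
    length = len(contig)
    hits = []
    for strand in "+-":
        seq = contig if strand == "+" else str(Seq(contig).reverse_complement())
        for s, e in _orfs_one_strand(seq, min_nt, max_nt, require_atg, include_stop):
            if strand == "+":
                start, end = s, e
            else:
                start, end = length - e, length - s
            protein = str(Seq(seq[s : e - 3]).translate())
            hits.append(
                OrfHit(
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    frame=s % 3,
                    nt_length=e - s,
                    protein=protein,
                )
            )
    if longest_per_stop:
        by_stop: dict[tuple[str, int], OrfHit] = {}
        for h in hits:
            key = (h.strand, h.end if h.strand == "+" else h.start)
            if key not in by_stop or h.nt_length > by_stop[key].nt_length:
                by_stop[key] = h
        hits = list(by_stop.values())
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def load_fbox_refs(path=None) -> list[tuple[str, str]]:
    """F-box exemplar panel as (id, protein) pairs (bundled default)."""
    if path is None:
        data = resources.files("srscout") / "data" / "synthetic_fbox_exemplars.fasta"
        with resources.as_file(data) as p:
            return load_fbox_refs(p)
    return read_fasta(path)


def score_fbox(
    protein: str,
    fbox_refs: Sequence[tuple[str, str]],
    tau: float = DEFAULT_FBOX_TAU,
) -> tuple[float, bool]:
    """Normalized best-exemplar similarity and the F-box verdict.

    score = max over refs of S(protein, ref) / S(ref, ref); the locus is
    called an F-box when score >= tau.
    """
    if not fbox_refs:
        raise ValueError("empty F-box reference panel")
    best = -math.inf
    for _rid, ref in fbox_refs:
        self_score = global_align_score(ref, ref)
        best = max(best, global_align_score(protein, ref) / self_score)
    return best, best >= tau


def _ref_seed_set(fbox_refs: Sequence[tuple[str, str]]) -> set[str]:
    seeds = set()
    for _rid, ref in fbox_refs:
        for i in range(len(ref) - _SEED_K + 1):
            seeds.add(ref[i : i + _SEED_K])
    return seeds


def find_disrupted_fbox(
    contig: str,
    fbox_refs: Optional[Sequence[tuple[str, str]]] = None,
    window_nt: int = DEFAULT_WINDOW_NT,
    step_nt: int = DEFAULT_STEP_NT,
    tau: float = DEFAULT_FBOX_TAU,
    contig_id: str = "",
) -> list[OrfHit]:
    """Find stop-disrupted F-box regions by translating through stops.

    A sliding window (default 1,200 nt, step 300) is translated in all
    six frames with stop codons kept as '*'.  A window is reported when
    it scores >= tau against the exemplar panel and contains a
    *disruptive* stop: one with exemplar-matching seed peptides on both
    sides, i.e. homology interrupted by the stop — the pseudogene
    signature.  The terminal stop of an intact gene has no homology
    beyond it and never qualifies, so intact genes are reported by
    ``find_orfs`` and never here.  Overlapping windows are merged.
    """
    contig = contig.upper()
    if fbox_refs is None:
        fbox_refs = load_fbox_refs()
    length = len(contig)
    window_aa = window_nt // 3
    step_aa = max(1, step_nt // 3)
    seeds = _ref_seed_set(fbox_refs)
    self_scores = [global_align_score(ref, ref) for _rid, ref in fbox_refs]

    raw: list[tuple[int, int, str, int, float]] = []  # start, end, strand, frame, score
    for strand in "+-":
        seq = contig if strand == "+" else str(Seq(contig).reverse_complement())
        n_runs = _n_runs(seq)
        for frame in range(3):
            n_codons = (len(seq) - frame) // 3
            if n_codons < window_aa:
                continue
            trans = str(Seq(seq[frame : frame + 3 * n_codons]).translate())
            # prefix sums of seed hits for the cheap screen
            seed_hit = [
                1 if trans[i : i + _SEED_K] in seeds else 0
                for i in range(len(trans) - _SEED_K + 1)
            ]
            hit_prefix = [0]
            for h in seed_hit:
                hit_prefix.append(hit_prefix[-1] + h)
            max_seed_start = len(seed_hit)
            for j in range(0, n_codons - window_aa + 1, step_aa):
                lo = min(j, max_seed_start)
                hi = min(j + window_aa - _SEED_K + 1, max_seed_start)
                if hi <= lo or hit_prefix[hi] - hit_prefix[lo] < _MIN_SEEDS:
                    continue
                nt_start = frame + 3 * j
                nt_end = nt_start + 3 * window_aa
                if _overlaps_any(nt_start, nt_end, n_runs):
                    continue
                window_trans = trans[j : j + window_aa]
                internal = False
                for k, aa in enumerate(window_trans):
                    if aa != "*":
                        continue
                    # seed support close to the stop on both sides; note
                    # flanks may extend past the window into the frame
                    def clamp(x: int) -> int:
                        return max(0, min(x, max_seed_start))

                    b_lo = clamp(j + k - _FLANK_AA)
                    b_hi = clamp(j + k - _SEED_K + 1)
                    a_lo = clamp(j + k + 1)
                    a_hi = clamp(j + k + 1 + _FLANK_AA)
                    if (
                        hit_prefix[b_hi] - hit_prefix[b_lo] >= _MIN_FLANK_SEEDS
                        and hit_prefix[a_hi] - hit_prefix[a_lo] >= _MIN_FLANK_SEEDS
                    ):
                        internal = True
                        break
                if not internal:
                    continue
                score = max(
                    global_align_score(window_trans, ref) / ss
                    for (_rid, ref), ss in zip(fbox_refs, self_scores)
                )
                if score < tau:
                    continue
                if strand == "+":
                    c_start, c_end = nt_start, nt_end
                else:
                    c_start, c_end = length - nt_end, length - nt_start
                raw.append((c_start, c_end, strand, frame, score))

    # merge overlapping windows per strand
    merged: list[OrfHit] = []
    for strand in "+-":
        intervals = sorted(r for r in raw if r[2] == strand)
        current: Optional[list] = None
        for c_start, c_end, _s, frame, score in intervals:
            if current is not None and c_start <= current[1]:
                current[1] = max(current[1], c_end)
                if score > current[3]:
                    current[2], current[3] = frame, score
            else:
                if current is not None:
                    merged.append(_merged_hit(contig, contig_id, strand, current))
                current = [c_start, c_end, frame, score]
        if current is not None:
            merged.append(_merged_hit(contig, contig_id, strand, current))
    merged.sort(key=lambda h: (h.start, h.end))
    return merged


def _merged_hit(contig: str, contig_id: str, strand: str, current: list) -> OrfHit:
    c_start, c_end, frame, score = current
    region = contig[c_start:c_end]
    if strand == "-":
        region = str(Seq(region).reverse_complement())
    trim = len(region) % 3
    protein = str(Seq(region[: len(region) - trim] if trim else region).translate())
    return OrfHit(
        contig_id=contig_id,
        start=c_start,
        end=c_end,
        strand=strand,
        frame=frame,
        nt_length=c_end - c_start,
        protein=protein,
        fbox_score=score,
        disrupted=True,
    )


def scan_haplotype(
    contig: str,
    rnase_loci: Sequence[tuple[tuple[int, int], str]],
    fbox_refs: Optional[Sequence[tuple[str, str]]] = None,
    flank_nt: int = DEFAULT_FLANK_NT,
    min_fbox: int = DEFAULT_MIN_FBOX,
    tau: float = DEFAULT_FBOX_TAU,
    contig_id: str = "haplotype",
    min_nt: int = DEFAULT_MIN_ORF_NT,
    max_nt: int = DEFAULT_MAX_ORF_NT,
) -> HaplotypeReport:
    """Assemble the S-locus candidacy report for one contig.

    ``rnase_loci`` are ((start, end), class_label) pairs in contig
    coordinates.  The contig is scanned for intact and disrupted F-box
    loci; hits outside every locus's ``flank_nt`` flank are dropped.
    The haplotype is a candidate S-locus iff some class III locus has at
    least ``min_fbox`` F-box loci in its flank.  Class I/II loci with
    many flanking F-boxes are noted but never make the contig a
    candidate.
    """
    contig = contig.upper()
    loci = sorted(rnase_loci, key=lambda t: t[0])
    for ((s1, e1), _c1), ((s2, e2), _c2) in zip(loci, loci[1:]):
        if e1 > s2:
            raise ValueError("overlapping RNase loci")
    if fbox_refs is None:
        fbox_refs = load_fbox_refs()

    all_orfs = find_orfs(
        contig, min_nt, max_nt, contig_id=contig_id, longest_per_stop=True
    )
    intact = []
    for orf in all_orfs:
        score, is_fbox = score_fbox(orf.protein, fbox_refs, tau)
        if is_fbox:
            orf.fbox_score = score
            intact.append(orf)
    disrupted = find_disrupted_fbox(
        contig, fbox_refs, tau=tau, contig_id=contig_id
    )

    def in_flank(hit: OrfHit, locus: tuple[int, int]) -> bool:
        s, e = locus
        return hit.start >= s - flank_nt and hit.end <= e + flank_nt

    fbox_loci = [
        h
        for h in sorted(intact + disrupted, key=lambda h: (h.start, h.end))
        if any(in_flank(h, locus) for locus, _cls in loci)
    ]

    candidate = False
    notes = [f"min_fbox={min_fbox}", f"flank_nt={flank_nt}"]
    for locus, cls in loci:
        n_near = sum(1 for h in fbox_loci if in_flank(h, locus))
        if cls == "III" and n_near >= min_fbox:
            candidate = True
        if cls in ("I", "II") and n_near >= min_fbox:
            notes.append(
                f"class {cls} RNase at {locus} has {n_near} flanking F-box "
                "loci; not an S-locus candidate"
            )
        s, e = locus
        flank_seq = contig[max(0, s - flank_nt) : min(len(contig), e + flank_nt)]
        n_frac = flank_seq.count("N") / max(1, len(flank_seq))
        if n_frac > 0:
            notes.append(f"flank of locus {locus}: {100 * n_frac:.1f}% N")

    return HaplotypeReport(
        contig_id=contig_id,
        rnase_loci=list(loci),
        fbox_loci=fbox_loci,
        candidate=candidate,
        min_fbox=min_fbox,
        notes=notes,
    )
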