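"""Conserved-region scanning and inclusion filters for T2/S-RNases.

T2-type ribonucleases carry five positionally ordered conserved regions
(here C1..C5).  Two of them are the active-site regions CAS I and CAS II,
each containing a catalytic histidine; the CAS II histidine is essential
for ribonuclease activity, so its absence marks a protein as inferred
non-functional.

Dataset-inclusion filters follow the family curation rule: keep coding
sequences longer than 350 bp that hit at least three of the five
regions.

Scoring: each region is represented by a small panel of equal-length
exemplar windows; a candidate window scores the best exemplar's
substitution-matrix sum normalized by that exemplar's self-score, so
1.0 is an exact exemplar match.  Reported hits are the best *collinear*
(panel-ordered, non-overlapping) selection of above-threshold windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

from Bio.Align import substitution_matrices

from srscout.seq_io import read_fasta

BLOSUM62 = substitution_matrices.load("BLOSUM62")

# candidates retained per region before collinear selection
_MAX_CANDIDATES = 50


@dataclass
class MotifProfile:
    """One conserved region: exemplar windows plus scoring parameters."""

    region_id: str
    exemplar_windows: list[str]
    cas_histidine_offset: Optional[int] = None
    score_threshold: float = 0.60

    def __post_init__(self) -> None:
        if not self.exemplar_windows:
            raise ValueError(f"{self.region_id}: no exemplar windows")
        length = len(self.exemplar_windows[0])
        if length < 4 or any(len(w) != length for w in self.exemplar_windows):
            raise ValueError(
                f"{self.region_id}: exemplar windows must share a length >= 4"
            )
        if self.cas_histidine_offset is not None and not (
            0 <= self.cas_histidine_offset < length
        ):
            raise ValueError(f"{self.region_id}: CAS offset outside window")

    @property
    def window_length(self) -> int:
        return len(self.exemplar_windows[0])


@dataclass
class MotifHit:
    """Best-scoring window for one region on one protein."""

    region_id: str
    start: int
    score: float
    histidine_present: Optional[bool] = None


def _window_score(window: str, exemplar: str, self_score: float) -> float:
    total = 0.0
    for a, b in zip(window, exemplar):
        total += BLOSUM62[a, b]
    return total / self_score


def _self_score(exemplar: str) -> float:
    return float(sum(BLOSUM62[a, a] for a in exemplar))


def scan_conserved_regions(
    protein: str, panel: Sequence[MotifProfile]
) -> list[MotifHit]:
    """Scan a protein for the panel's conserved regions.

    Returns at most one hit per region.  Hits are the score-maximal
    collinear subset: region order along the protein must follow panel
    (N->C) order and windows must not overlap; lower-scoring
    out-of-order candidates are dropped.  A protein shorter than a
    region's window simply yields no hit for that region.
    """
    candidates: list[list[MotifHit]] = []
    for profile in panel:
        wlen = profile.window_length
        self_scores = [_self_score(w) for w in profile.exemplar_windows]
        found = []
        for start in range(0, len(protein) - wlen + 1):
            window = protein[start : start + wlen]
            score = max(
                _window_score(window, ex, ss)
                for ex, ss in zip(profile.exemplar_windows, self_scores)
            )
            if score >= profile.score_threshold:
                his = None
                if profile.cas_histidine_offset is not None:
                    his = window[profile.cas_histidine_offset] == "H"
                found.append(
                    MotifHit(
                        region_id=profile.region_id,
                        start=start,
                        score=score,
                        histidine_present=his,
                    )
                )
        found.sort(key=lambda h: (-h.score, h.start))
        candidates.append(found[:_MAX_CANDIDATES])

    return _best_collinear(candidates, [p.window_length for p in panel])


def _best_collinear(
    candidates: list[list[MotifHit]], window_lengths: list[int]
) -> list[MotifHit]:
    """Choose <=1 candidate per region maximizing total score subject to
    panel-ordered, non-overlapping placement (ties: more hits, leftmost)."""
    # best[(region_index, candidate)] -> (score, n_hits, chain)
    best_chains: list[tuple[float, int, list[tuple[int, MotifHit]]]] = [(0.0, 0, [])]
    per_region: list[list[tuple[float, int, list[tuple[int, MotifHit]]]]] = []
    for r, cands in enumerate(candidates):
        entries = []
        for hit in cands:
            best_prev: tuple[float, int, list] = (0.0, 0, [])
            for pr in range(r):
                for score, n, chain in per_region[pr]:
                    prev_end = chain[-1][1].start + window_lengths[chain[-1][0]]
                    if prev_end <= hit.start and (score, n) > best_prev[:2]:
                        best_prev = (score, n, chain)
            entry = (
                best_prev[0] + hit.score,
                best_prev[1] + 1,
                best_prev[2] + [(r, hit)],
            )
            entries.append(entry)
        per_region.append(entries)
        best_chains.extend(entries)
    best = max(best_chains, key=lambda e: (e[0], e[1]))
    return [hit for _, hit in best[2]]


def passes_inclusion_filter(cds_length: int, hits: Sequence[MotifHit]) -> bool:
    """Family-curation rule: CDS longer than 350 bp and >=3 of the five
    conserved regions hit."""
    regions = {h.region_id for h in hits}
    return cds_length > 350 and len(regions) >= 3


@dataclass
class CatalyticStatus:
    """Tristate catalytic-histidine evidence.

    Each field is True (present), False (absent) or None (region not
    hit, so undetermined).  ``inferred_functional`` is False when the
    CAS II histidine is absent, None when the CAS II region was not
    found, True otherwise.
    """

    cas1_his: Optional[bool]
    cas2_his: Optional[bool]
    inferred_functional: Optional[bool]


def catalytic_histidines(
    hits: Sequence[MotifHit], panel: Optional[Sequence[MotifProfile]] = None
) -> CatalyticStatus:
    """Infer catalytic competence from the CAS I/II histidines."""
    if panel is None:
        panel = default_motif_panel()
    cas_regions = [p.region_id for p in panel if p.cas_histidine_offset is not None]
    if len(cas_regions) != 2:
        raise ValueError("panel must mark exactly two CAS regions")
    by_region = {h.region_id: h for h in hits}
    cas1 = by_region.get(cas_regions[0])
    cas2 = by_region.get(cas_regions[1])
    cas1_his = cas1.histidine_present if cas1 is not None else None
    cas2_his = cas2.histidine_present if cas2 is not None else None
    if cas2_his is None:
        functional = None
    elif cas2_his is False:
        functional = False
    else:
        functional = True
    return CatalyticStatus(
        cas1_his=cas1_his, cas2_his=cas2_his, inferred_functional=functional
    )


def load_motif_panel(fasta_path, tsv_path) -> list[MotifProfile]:
    """Load a motif panel from exemplar FASTA (ids ``REGION|n``) and a
    region TSV with columns (region, cas_offset or '-', threshold)."""
    windows: dict[str, list[str]] = {}
    for name, seq in read_fasta(fasta_path):
        region = name.split("|")[0]
        windows.setdefault(region, []).append(seq)
    panel = []
    with open(tsv_path) if not hasattr(tsv_path, "read") else tsv_path as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            region, cas, threshold = line.split("\t")
            if region not in windows:
                raise ValueError(f"region {region} has no exemplar windows")
            panel.append(
                MotifProfile(
                    region_id=region,
                    exemplar_windows=windows[region],
                    cas_histidine_offset=None if cas == "-" else int(cas),
                    score_threshold=float(threshold),
                )
            )
    return panel


def default_motif_panel() -> list[MotifProfile]:
    """The bundled five-region panel (synthetic consensus exemplars)."""
    data = resources.files("srscout") / "data"
    with resources.as_file(data / "motif_panel.fasta") as fasta_path, resources.as_file(
        data / "motif_panel.tsv"
    ) as tsv_path:
        return load_motif_panel(fasta_path, tsv_path)
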