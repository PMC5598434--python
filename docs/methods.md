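# Methods

## Isoelectric point

Net charge is modelled as a sum of independent Henderson–Hasselbalch terms,
one per ionizable group: the N-terminal amine and H/K/R side chains
(positive), the C-terminal carboxyl and D/E/C/Y side chains (negative).
Q(pH) is strictly decreasing, so the isoelectric point — the pH of zero
average charge — is the unique root, bracketed by bisection on [0, 14] to a
default tolerance of 0.01 pH and reported to two decimals.

The default dissociation constants are the Bjellqvist set as popularized by
the ExPASy lineage of tools (side chains D 4.05, E 4.45, H 5.98, C 9.00,
Y 10.00, K 10.00, R 12.00; C-terminus 3.55 with overrides D 4.55, E 4.75;
N-terminus 7.50 with overrides A 7.59, M 7.00, S 6.93, P 8.36, T 6.82,
V 7.44, E 7.70). pK dialects exist, so the table is replaceable via a TSV.
X residues carry no charge. Signal peptides are excluded when a cleavage
boundary is supplied; the toolkit deliberately does not *predict* boundaries,
and dataset-level pI summaries depend on how they were delimited.

## Conserved regions and the inclusion filter

Each of the five family regions C1–C5 is represented by a small panel of
equal-length exemplar windows. A candidate window's score is the best
exemplar's BLOSUM62 sum over the ungapped window divided by that exemplar's
self-score (1.0 = exact exemplar match). Because the five regions are
positionally ordered in all described family members, the reported hits are
the score-maximal *collinear* selection — one window per region, region order
following panel order, windows non-overlapping — found by dynamic selection
over all above-threshold candidates.

The bundled panel is synthetic: consensus-like exemplars built around the
family's canonical active-site cores (CAS I containing HGLWP, in region C2;
CAS II containing KHGTC, in region C3), shipped as data, not code. The
per-region threshold (0.60) was set once at the ~99.7th percentile of the
panel's best-window score distribution on random 100-residue sequences, so a
random protein essentially never hits any region while windows up to roughly
25% diverged from an exemplar still do. Users with a curated panel for their
clade should supply it together with thresholds calibrated the same way.

Inclusion filtering follows the family curation rule: keep sequences whose
coding region exceeds 350 bp and that hit at least three of the five regions.
Catalytic competence is a tristate read off the CAS regions: the CAS II
histidine is essential for ribonuclease activity, so its absence marks the
protein as inferred non-functional; an unhit CAS II region leaves the call
undetermined rather than negative.

## Intron architecture

An intron is anchored by the count of coding nucleotides 5′ of it (strand-
agnostic) and, in an alignment, by the column of the first coding nucleotide
3′ of it. Its phase is that count mod 3: phase 0 before a codon, phases 1 and
2 after the first or second base. Sites from one alignment are clustered into
homologous positions by single linkage with a link whenever two anchor
columns fit inside a seven-nucleotide window (|Δcolumn| ≤ 6); the window is
measured in alignment columns including gap columns. Phase conflicts inside a
cluster are flagged and reported, never merged away — in land plants the
canonical positions show no phase variation, so a conflict signals either a
mis-anchored intron or a genuinely novel site.

Clusters are matched to the eleven canonical land-plant positions through a
bundled reference site table; unmatched clusters get labels from 12 upward.
The reference phases for positions 3 (+2), 5 (+0), 8 (+0) and 10 (+0) follow
the family literature; the remaining phases in that table are fixed
reference-frame conventions used by the synthetic fixtures, and are
documented as such in the data file. The pattern catalog names the eight
observed presence sets (I-A {2}, I-B {5}, I-C {2,5}, I-D {2,5,9}, II
{3,4,5,6,7,8,10,11}, III-A {5,9}, III-B\* {9}, III-C {5}, III-D {1,5});
III-B\* is flagged provisional, being predicted from genomic sequence without
expressed-sequence support. A single intron at position 5 is genuinely
ambiguous between I-B and III-C and is reported as both.

## Classification

Three evidence lines feed the call: the intron pattern matched against the
catalog, the pI side (acidic ⇒ I/II, basic ⇒ III, boundary 7.0), and the
majority class among the k = 3 nearest labeled exemplars under the alignment
distance d(a,b) = 1 − S(a,b)/min(S(a,a), S(b,b)), where S is the global
(Needleman–Wunsch) score with BLOSUM62 and affine gaps (open −10, extend −1;
a gap of length L costs open + (L−1)·extend). The nearest-reference rule is a
deterministic, implemented stand-in for likelihood-based tree placement;
distances ≥ 0.95 to every exemplar mark the panel uninformative.

The ladder: a pattern uniquely matching one class decides alone
("pattern-exact"); otherwise the pI side and the exemplar label vote, with
"multi-line" confidence when at least two lines agree and "single-line"
otherwise; unresolvable ties are "unclassified". The S-RNase candidate flag
requires class III, pI ≥ 8.0 (functional S-RNases rarely sit below), an
S-compatible intron pattern — III-C, III-D, or undetermined for cDNA input,
but never III-A, because known S-RNases lack position 9 — an intact (or
undetermined) CAS II histidine, and at least three conserved regions.
Taxonomy is never enforced: class III is reported wherever the evidence says
so, and the core-eudicot restriction is the user's interpretive context.

## S-locus scanning

Intact F-box candidates are ATG..stop ORFs of 900–1800 nt (stop included,
bounds inclusive; both conventions configurable since the field's are not
standardized) on either strand. Every ATG is walked to its next in-frame
stop; for reporting, hits are deduplicated to the longest in-bounds ORF per
(strand, stop). Codons containing isolated N translate to X and do not stop
the walk; runs of ≥ 10 N are treated as assembly gaps that break ORFs and
windows, and the N fraction of each flank is noted in the report. A
candidate ORF is an F-box when its translation scores ≥ τ = 0.25 against an
exemplar panel (score = max over refs of S(p, ref)/S(ref, ref)).

Pseudogenized copies are found by sliding a 1,200-nt window (step 300) over
all six frames, translating *through* stops. A cheap screen (shared 5-mer
peptides with the exemplars, prefix-summed per frame) selects windows worth
aligning. A window is reported when it scores ≥ τ and contains a
*disruptive* stop: one with at least three exemplar seed matches within 50
codons on **each** side. This "homology interrupted by a stop" requirement is
what distinguishes a pseudogene from the terminal stop of an intact gene
followed by unrelated sequence; overlapping windows are merged into one
disrupted region.

A haplotype is an S-locus candidate when at least `min_fbox` = 4 F-box loci
(intact or disrupted) lie within the 2 Mb flank of a class III RNase locus.
The value 4 operationalizes "more than a few" and is configurable and echoed
in every report. Class I/II RNase loci with many flanking F-boxes — a real
phenomenon in plant genomes — are reported with a note but never make the
contig a candidate.

## Synthetic fixtures

The generator emulates the *statistical* structure of the family, not its
molecular evolution. Proteins are a fixed ~120-residue backbone: one exemplar
window per conserved region joined by class-specific linkers (so every
generated protein hits all five regions), with linker residues hill-climbed
(single mutations, including histidine for fine charge steps near neutral
pH) until the pI is within 0.3 of a target drawn from the class distribution
— class I and II from Normal(5.5, 0.8), class III from Normal(8.8, 0.7),
truncated to (3.9, 9.9), mirroring the family's acidic/basic split. Patterns
are drawn per class (I: mostly I-D; II: always II; III: mostly III-C), genes
insert GT..AG introns at the canonical offsets with a ±1-codon
phase-preserving jitter, and the alignment rows are the back-translated CDS
in a fixed 363-column reference frame. Haplotype contigs plant an RNase gene
and intact/disrupted F-box ORFs (lengths uniform in bounds; disruption = one
internal codon mutated to TGA, placed so neither flanking fragment reaches
900 nt) on random strands over an i.i.d. uniform background, with ≥ 2 kb
clearance between features so sliding windows never bridge two of them.
Everything is deterministic per (spec, seed).

What the fixtures do **not** model: codon usage, substitution processes along
a tree, indels, alignment uncertainty, real intergenic composition, or real
F-box domain architecture (the bundled F-box exemplars are synthetic random
proteins, and the class exemplar panel is generated from the same backbone).
Passing tests therefore demonstrate that the machinery is correct and
internally consistent — filters enforced exactly, planted truth recovered,
oracles matched — not that the bundled panels are sensitive enough for any
particular real clade; for real analyses, users should swap in curated motif,
class and F-box panels.

## Numerical choices and degenerate inputs

Bisection uses fixed bounds [0, 14] and errors if the charge curve has no
sign change (impossible with both termini present). Cluster labels are
assigned in ascending column order; ties at cluster boundaries resolve by
column then gene id. The collinear motif selection maximizes total score,
then hit count. Empty FASTA files, duplicate ids, overlapping exons or RNase
loci, out-of-contig exons, and signal-peptide boundaries that leave no mature
chain are hard errors; untranslatable nucleotide records in batch
classification produce per-record error rows and the run continues. Proteins
shorter than a motif window simply yield no hits. The acceptance script
scales everything to desk size (100-protein oracle checks, 30/300-record
panels, 20 two-megabase haplotypes, 50 ten-kilobase ORF contigs), chosen so
the full verification runs in minutes on one CPU.

## Known limitations

* Class calls degrade gracefully but meaningfully without gene structures:
  cDNA input leaves the pattern undetermined, so the call leans on pI and the
  exemplar panel alone, and acidic queries without references come back
  unclassified rather than guessed.
* The seven-nucleotide window rule is applied column-inclusive (gap columns
  count); the alternative reading (|Δ| ≤ 7) is exposed as a parameter but not
  the default.
* Whether the original 900 bp–1.8 kb ORF bounds counted the stop codon, and
  whether ORFs had to start with ATG, is not standardized; both are
  configurable, defaults as above.
* The nearest-reference rule is a stand-in for phylogenetic placement and
  inherits the bundled panel's coverage; it reports "unclassified" outside
  its competence rather than extrapolating.
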