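# srscout

A toolkit for characterizing plant **T2/S-type ribonucleases** and hunting for
putative (possibly relict) **S-loci** in genome assemblies.

The T2/S-RNase family of land plants falls into three phylogenetic classes
that differ in structure and function:

* **class I** — widespread, typically acidic proteins; most genes carry three
  introns at the canonical positions 2, 5 and 9 (pattern I-D);
* **class II** — widespread, acidic; invariably eight introns, at positions
  3, 4, 5, 6, 7, 8, 10 and 11, seven of which occur in no other class;
* **class III** — restricted to core eudicots, typically basic. All known
  S-RNases — the pistil-side specificity determinants of RNase-based
  gametophytic self-incompatibility (GSI) — belong to this class, and almost
  all carry a single intron at position 5 but not 9 (patterns III-C, or III-D
  with an extra intron at position 1 in *Prunus*).

An S-locus couples one S-RNase with several tightly linked pollen-expressed
F-box genes (SLF/SFB). After a lineage loses self-incompatibility the locus
decays: F-box copies accumulate in-frame stop codons but remain recognizable —
a relict signature this toolkit detects.

## What the package computes

| module | computation |
| --- | --- |
| `physchem` | Bjellqvist isoelectric point: the root of Q(pH) = Σ<sub>pos</sub> m<sub>i</sub>/(1+10^(pH−pK<sub>i</sub>)) − Σ<sub>neg</sub> m<sub>j</sub>/(1+10^(pK<sub>j</sub>−pH)), by bisection on [0, 14]; signal peptides excluded when a cleavage boundary is given |
| `motifs` | hits to the five conserved family regions (C1–C5, with the CAS I/CAS II catalytic histidines), the "> 350 bp and ≥ 3 of 5 regions" inclusion filter, and catalytic-competence inference from the CAS II histidine |
| `intron_arch` | intron insertion points mapped to alignment columns, clustered into homologous positions by the seven-nucleotide window rule (single linkage, \|Δcolumn\| ≤ 6), phases (offset mod 3), presence matrices and the canonical pattern catalog |
| `classify` | class I/II/III calls from intron pattern, pI side (acidic/basic at 7.0) and nearest labeled exemplar (global-alignment distance), plus the S-RNase candidate flag (class III ∧ pI ≥ 8.0 ∧ S-compatible pattern ∧ intact CAS II ∧ ≥ 3 regions) |
| `slocus_scan` | six-frame ORF scan (900–1800 nt, ATG..stop), F-box similarity scoring against an exemplar panel, detection of stop-disrupted (pseudogenized) F-box copies, and the S-locus candidacy verdict: a class III RNase locus with ≥ 4 F-box loci within its 2 Mb flank |
| `synth_fixtures` | deterministic synthetic proteins, gene structures, alignments and 2-Mb haplotype contigs with known truth |

## Worked example

Generate a labeled synthetic panel and classify it:

```bash
scout simulate --seed 3 --out fixtures
scout classify fixtures/proteins.fasta \
    --genes fixtures/genes.gff3 --contigs fixtures/gene_contigs.fasta \
    --alignment fixtures/alignment.fasta --no-refs
```

Output (columns 1–8, abridged):

```
id      class  confidence     pI    pattern    regions_hit  cas2     candidate
I_001   I      pattern-exact  4.8   I-D        5            present  False
I_004   I      multi-line     4.72  I-B/III-C  5            present  False
II_009  II     pattern-exact  6.24  II         5            present  False
III_002 III    pattern-exact  9.4   III-D      5            present  True
III_007 III    multi-line     9.18  I-B/III-C  5            present  True
III_003 III    pattern-exact  7.01  III-D      5            present  False
```

Reading the rows: `I_001` has the three-intron I-D pattern, unique to class I —
the call is decided by the pattern alone ("pattern-exact"). `I_004` carries a
single intron at position 5, which class I and class III share (I-B vs III-C);
its acidic pI (4.72) breaks the tie toward class I with two agreeing evidence
lines ("multi-line"). `III_002` is basic (pI 9.4) with the *Prunus*-style
III-D pattern and an intact CAS II histidine — an S-RNase candidate.
`III_003` is class III but below the pI 8.0 bar that functional S-RNases
rarely cross, so it is not flagged.

Scanning a genome contig around known RNase loci
(`loci.tsv`: contig, 1-based start, end, class):

```bash
scout scan-slocus fixtures/haplotype.fasta --rnase-loci loci.tsv --out report.tsv
```

emits a report of RNase and F-box loci with strands, disrupted flags and
inter-gene distances in kb, plus the haplotype's candidacy verdict.

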