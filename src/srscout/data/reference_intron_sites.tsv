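# Canonical land-plant T2/S-RNase intron positions in the bundled
# reference alignment frame (columns are 0-based nucleotide alignment
# columns of the first coding base 3' of the intron).  Phases for
# positions 3, 5, 8 and 10 follow the family literature; the remaining
# phases are fixed reference-frame conventions used by the synthetic
# fixtures.  Position 11 columns assume the ~120-codon reference
# backbone.
# position	column	phase
1	30	0
2	61	1
3	92	2
4	120	0
5	150	0
6	181	1
7	212	2
8	240	0
9	270	0
10	300	0
11	331	1
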