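# Synthetic default panel for the five conserved T2/S-RNase regions.
# Exemplar windows (motif_panel.fasta) are design-choice consensus-like
# stand-ins built around the canonical RNase T2 active-site cores
# (CAS I: HGLWP; CAS II: KHGTC); they are data, not code, and can be
# replaced by a user panel.
# region	cas_offset	threshold
C1	-	0.60
C2	3	0.60
C3	1	0.60
C4	-	0.60
C5	-	0.60
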