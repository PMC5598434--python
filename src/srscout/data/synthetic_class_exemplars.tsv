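# Synthetic class exemplar labels (stand-in reference panel).
ref_I_1	I
ref_I_2	I
ref_I_3	I
ref_II_1	II
ref_II_2	II
ref_II_3	II
ref_III_1	III
ref_III_2	III
ref_III_3	III
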