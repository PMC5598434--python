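>C1|1
TFDYFQFVQ
>C1|2
TFDYLQFVQ
>C1|3
SFDYFQLVQ
>C2|1
FTIHGLWPS
>C2|2
FTLHGLWPS
>C2|3
YTIHGLWPQ
>C3|1
KHGTCSEKT
>C3|2
KHGTCSELT
>C3|3
RHGACSEQT
>C4|1
WNYSDIVSP
>C4|2
WNYTDIVSP
>C4|3
WNYSDIVAP
>C5|1
PVIQCQPNQ
>C5|2
PVIRCQPNQ
>C5|3
PVLQCQPDK
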