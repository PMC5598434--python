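>fbox_ref_a
MLLYDHGQFDRAMCDDWVDCYRHTVANCHKRVRPASIMCWFICPAECGSRGHPHHSCDFS
QDLWAEHHMVNEAGNMTDCTPPRLSCFDNGPGVWEIWGWSDNFQKTEPQGHYAPVKEMVY
KVHVEHQLSEFHIAKVVRMPPHRLAKMNGDYGIPQAGDGWSQCPTGQFDLWMFGEGNPHG
SWIHDEANPKCPNWCWKKQECNVAFRGEDFQETHLNSVRAQAMYALDYPMATWNAPSCYH
YITNCAAFICHQTENSYNPLLPMPPCQMHAQHTNNFHTGSEIEPDWAMSPFDNYAGRMQP
TWFFCMYMCICRNPHDLNHR
>fbox_ref_b
MYAMICWKHMMGPVHAMSNYMCAKMGSANKERGPKEFNQMDRLPRKKAHIRHFGIPDNAD
NQHQHVIVWQEEWMTHAFSMYENSLWTLTAHVPGVGNIVKKKHFVWENRFQGVTAMANQR
YKSLSDQEWVPPNYSRIGCGSMGRMAELCTCSFFCWYECIGQIKKERENMEYHREAYQVY
PASAERNKGSRKHLKNNIMFVECCSPFDRPKVYMRFTCRANIHWSFKLGKQMWCKSKISF
MWSVSEGDYCPCTEFQIMYHKYNEHYLFEPIKPKHPQVNFYLHTESRDKDSNFQYDQLWT
QNEVNECGACRANNHYMNEVVGYFHTNEWKRYYGPVIDFDCLAEPRWHILYITIWFKRSI
LWRAKKSMSEWSGRIWYVRQDYGLLLMNMAEVVKHLMGGVYDYTGESDACPHCERTIDDN
EAHETLEPFNYVWCWKPEGYHPHDKRVTID
>fbox_ref_c
MSYREDFMFIYYHDFHIKEQNQRWMMPNIRMVIGVHIAVFAFKTENIGFNGIGMDTMAKA
AREPEPYVIPRCELGRNRNGWSWHFVMISTDGVAHCKEGTLWNTGIFPQFRFKRVDKAGS
MPFYRHFGGCTWLYQIRKPPGMAKNVLLGQWCHGCGEVLPMVDPHMEMTNYAPRYDAVLL
EWSGRRSCNNIVNGLKCQDSSRHRDKMERCWIFDQLNCQYSDGFYMNYQFTIPHRFEYLY
YHKEFCQVQYVQITLSGSFFCICEAGPGVSQYHPRGIENPMMDVDESFTWQPANWWDGRG
KSLRTDLFEYLKRERETINTNFINQKRFDWVSVETQGICANDDFWFSVADICYQRMWLLV
IKYALQHYGWHWNYEPNFWVINSYICLVDKRPGHILGWNVNWMARRTKDRRWCMKQIFYR
RVNQNKIFGSIGSNWAYKQWNRNPEGPDTQDVWMILCPCLDTGYYKTGRQPHMKHGHPFY
TREETIGGHSAVGKVIHDWFDMPASLEASECCEVMGAAQSICKNWFMATRPVCLQWDDII
QKWDCTTTCDPFNPMRTSPTMLQFCIILDWPWPVGGLEKL
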