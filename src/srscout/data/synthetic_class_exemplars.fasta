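>ref_I_1
LKPNPFNIILNETFDYFQFVQFESNNLPGGKLPYTIHGLWPQSLVAFKPIDNNLRHGACS
EQTQPQSIVANLQAFWNYSDIVSPGKEDQPPQNKSDPVLQCQPDKRGEVIQSFGNDQTVE
>ref_I_2
LKENEENIILNETFDYFQFVQTESNSKPVDDLPFTLHGLWPSSQVAFKPIKNNLKHGTCS
EKTQPQLIVANLAAQWNYTDIVSPGDPDQPPQNKQKPVLQCQPDKNGELIKSFGNKQTVF
>ref_I_3
LKPNSFNIIKNVTFDYFQFVQFSSNSVLNDNLPYTIHGLWPQSQGAFEPIKNNLKHGTCS
ELTQPILIVANLAAGWNYTDIVSPGDEDQEPQNKQDPVIQCQPNQNGEVAKSFGNDQTVF
>ref_II_1
TLNQGEGPSLLQTFDYFQFVQEVQPQTRKELGFFTIHGLWPSPVRGNVFQPTSQRHGACS
EQTNEAPRSQPTPQQWNYSDIVSPPAFVQGNTKNSNPVIQCQPNQTDQKATQPTELVRPE
>ref_II_2
TLNQGDGPSLLQTFDYLQFVQLKQDKTEEREGFFTIHGLWPSPDELVVQQPKSQKHGTCS
EKTQEAPKSQPTAQQWNYSDIVSPPAFVQGTVKNSNPVIQCQPNQTKTKGTQGTKLVDPQ
>ref_II_3
TLNQGDGASLLQSFDYFQLVQLVTRKTERDLGFFTLHGLWPSFVEVNVQQPTSQRHGACS
EQTQEAPKSQPTPQQWNYSDIVSPPAFVQGTEDNSNPVIRCQPNQTKTKAIQGTKLLDGE
>ref_III_1
NGENQDGSFRKSTFDYFQFVQVQSVQTVLALPTYTIHGLWPQFRQVKTGVRGAGKHGTCS
ELTFKPNGAAIKLEQWNYTDIVSPGSPQTTLIPTTIPVIQCQPNQLIAIRPGNAFGDIKP
>ref_III_2
NGREQGGGFKKSSFDYFQLVQPQRLQTVLALPTFTLHGLWPSVKQVKRGVEGAGKHGTCS
ELTFKPTGAASSLEQWNYSDIVAPGSPQTTLIKATIPVLQCQPDKLIKPDPGNAFGKIEP
>ref_III_3
NGEGQKGGFKKSTFDYFQFVQPQDDQTVLAESLYTIHGLWPQNEQGKQGVEGAGKHGTCS
ELTFKPTGEAISNRRWNYSDIVAPFSPQKTLIFATIPVIQCQPNQLIKIRPGNAFGRITS
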