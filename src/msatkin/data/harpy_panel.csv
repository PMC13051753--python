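locus,motif,repeat_count,primer_forward,primer_reverse,expected_size,annealing_temp,n,n_alleles,ho,he,p_hwe,q_exclusion,i_identity
Hha01,AC,10,CTCCTGTGTTCCCATCTGCT,GGGTGCGAGACAGTTCCTC,158,59,24,2,0.2727,0.2410,1.000,0.1759,0.6121
Hha02,AC,10,TCTGTTGGAGTTTCCGGAGC,CCGGGATGCATCTCCTTTGT,192,59,24,8,0.5000,0.8266,0.000,0.7517,0.0837
Hha03,AG,14,ATGGCAAGTCGCTAGAACGG,GGCTGCTATTCCACTTGCCA,204,57,24,5,0.5454,0.6797,0.003,0.5037,0.2176
Hha04,AC,12,GTGGAAGGGAGTTAGCGTGG,ATGGCTCTGTCTAACCTGCG,125,59,24,2,0.0454,0.0454,1.000,0.0420,0.9141
Hha05,AGC,11,ACAAGGTCACATCTTCCCGC,AAACTGTTCTGCCTCGCTGA,179,59,24,8,0.5000,0.5549,0.231,0.4602,0.3149
Hha06,AG,12,ACCAGGCTGTAAGGGTTGAAG,TGGACAGATGTGGAGTGTCG,121,59,24,4,0.8636,0.6839,0.000,0.5438,0.1777
Hha08,AC,10,CATCCGTAGCCATGCACAGA,CTTACCTGGGTGTCAGCACA,155,57,24,4,0.2727,0.3541,0.218,0.3067,0.4545
Hha09,AC,12,ACCCAAGCTCTTCCTGGATG,TCAAAGCGTATGAAGCCAGGA,198,57,24,4,0.0909,0.4904,0.000,0.3990,0.3233
Hha12,AG,11,TCCTCCTTGGAAGCAGCAAG,AGCTCAGTTTCTGGAGTCAGG,120,57,24,3,0.3181,0.3689,0.225,0.2654,0.4595
Hha18,AC,11,GCCCACAGAAACGATACAGC,ATTAGCTGCTCGCAGACAAA,150,57,24,4,0.2272,0.2896,0.265,0.2684,0.5279
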