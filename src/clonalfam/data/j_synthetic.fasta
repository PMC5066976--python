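>IGHJS-1*01|anchor=12
CACATAGACTGGTGGAACGCCCTAGTA
>IGHJS-2*01|anchor=12
GGCTGCCATTCTTGGTTAATAATCGAG
>IGHJS-3*01|anchor=12
CCCCCCGAATTCTGGGATTGTCTGGTG
>IGHJS-4*01|anchor=12
TCCTGCCTAGGGTGGGTTCGAGTGCTG
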