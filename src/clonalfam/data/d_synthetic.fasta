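>IGHDS-1*01
AGCGTGACGGCAGTAT
>IGHDS-2*01
CTCCGGGTCTGGGATT
>IGHDS-3*01
GCAACGTCCGTATCAT
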