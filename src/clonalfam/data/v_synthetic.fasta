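>IGHVS-1*01|anchor=84
GAGAGCGCTCAGATACTACTATTGGACATTACGGCCCGGCCCCCAACATCCCAGCGGCATTGCTTAATTCCTTACGTCTCGACCTGTCAGTTTGCT
>IGHVS-2*01|anchor=84
TAAAAGCTATTTGCCTAGTTTGGGACGCTCTCCTCAGTTTCCAACAAACCAGGGTAGATAGAAGACCCTCAATGAGCTGTCAAGTGTTAGGTAGGC
>IGHVS-3*01|anchor=84
TGATCTTTGATGAATTAGGGGAGCCCCCGTGGCTTATGAAAGGATCGGACTTTTCCTCCATTCAGTACGAGACCTTAGCCTTATTGTTTACAAAAG
>IGHVS-4*01|anchor=84
GGCTAGAGGAGATTACGCAGGACACCCCAAACTGGTGCAACTCTCCGGTTCTATATAGTATAAGGACATTGGCTCTGGCAAACCTGTCCGAACATT
>IGHVS-5*01|anchor=84
TAATCACGAGTTCGGCCGCTAGTAGATGGTATCCTGTTCTCGATCTTGAGCGCCCGAGTGACTAGCATAGGGATATTACCCTCTTGTTACGTACCT
>IGHVS-6*01|anchor=84
CATTCATCTGAAACGCTTATAAACTACTACGATCGATTCGGAACTAGATGCACGGTCCAGCGCGATGTTTACGATGGCGTGTACTGTACTTGCGGC
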