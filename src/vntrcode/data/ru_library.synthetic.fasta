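>A||shared|PARENTS=
CGCTTGGATCGCCGCCCGGCGCGAGTCGGGTCGGGCGGCC
>B||shared|PARENTS=
GCCATGCATGCTCATGGCCCGGACGGCAGCGTACCGTGC
>C||shared|PARENTS=A
CGCTTGGATCGCCGCCCGCGAGTCGGGTCGGGCGGCC
>D||LAVA|PARENTS=A
CGCTTGGATCGCCCCACGGGGGGACTCACGTCGGCCGCCT
>E||SVA|PARENTS=B
GCTCACGCATGGTCGTTGGCCCGTATGGCACCGTACTGTGC
>G||SVA|PARENTS=B
GTGCAGCATTCTCATTGCCCGGGCGGCAACGTCCCTGTCGC
>H||SVA|PARENTS=A
CGATTGGTTCTCAGCCCGGCGAGAGTCGGGCTTCGCGGGGCC
>I||SVA|PARENTS=H
GGGAATGGTTCTCAGTTCCGGCCGAGAGTCTGGTCTTCGCCGGGGCG
>F||SVA|PARENTS=I
GTGAATGGTTCTTCAGTTACGGCTAAGATTCTGGGCTTCGCCGGGGCA
>K||SVA|PARENTS=I
GGGAATGGTTATCATTTCCGGGCCGACCGCCTGGTGGTCACCGGGGGAG
>L||SVA|PARENTS=K
GGGAATGGTTAACAGTTCCGGGCCGAGCGTCTGGTCGTCTCCCGGCGTAG
>J||SVA|PARENTS=A|NOTE=figure-only
CGCCATTGGATCGCCCCCAGGCCCGTAGTGGGGTCCGGGAGGAC
>M||LAVA|PARENTS=B|NOTE=figure-only
GCTCATGTCATCCCTCCATGCGCGCTGACGACGGACTATCCGTGC
>N||LAVA|PARENTS=D
CAGCCTTCAGGGATGCGCACCTAAAGGGGTGGACCTCAGCGTTCGGGCAGCCA
>O||LAVA|PARENTS=B
GCCTTACATGCACATGGCCGCGGACGGGCGGGTAACCACGCA
>P||LAVA|PARENTS=O
GCCTTACATGCATATGGCCACTAACGGGCGGGGAATCCGCCC
>Q||orangutan_SVA|PARENTS=B
GCTAAGCATGCTGCATTGCCCGTCTCGGATGCCGTACTCTTGC
>R||orangutan_SVA|PARENTS=B
GCCATGCAAGATCATGGACCGGAGGGCAGTTTAACTAC
>S||chimp_SVA|PARENTS=|UNDERIVED=true|NOTE=derivation-undetermined
TTGGATTAAAGGTTCAATGTAATTCCGGGTCTGCTCATGAT
>T||SVA|PARENTS=C|TERMINAL=true
CGCTCGATCCGCGCCCGCGAGTAGGGTCGTGCGGTC
>A|5'|shared|PARENTS=|NOTE=LAVA 5'-terminal A differs from internal A
CGCTTGGATCGCCGCCCGGCGCGAGTCGACTCGGGCGGCC
>B|'|shared|PARENTS=|NOTE=second B-type repeat, SVA_B-F 5' arrays
GCCATCCATGCTCAAGGCCCGGACGGCAGCGTACCGTGC
>B|5'|shared|PARENTS=|NOTE=5'-most B-type RU, orangutan SVA / LAVA_B2
GCCATGCATGCTCATGGCCCGGAGGGCCGCGTACGGTGC
>B|CCA|shared|PARENTS=|NOTE=subfamily-specific internal B, LAVA_B2C
GCCATGCAAGCTCAGGGCCCGGACGGCAGCGTACCGTAC
>C|'|shared|PARENTS=|NOTE=short C of the SVA_D-F internal/3' KGC' arrays
CGCTTGGATCGCTGCCCGCGGGTCGGGTCGGGCGGCC
>C|''|shared|PARENTS=|NOTE=alternative short C, SVA_E LL'GC'/C'' arrays
CGTTTAGATCGCCGCCCGCAAGTCGGGTCGGGCGGCC
>C|T|shared|PARENTS=|NOTE=sub-terminal C variant, LAVA_B1A onwards
CGCTTGGATCGCCGCCCGCGAGTCTGGTTGGGCGGCC
>C|TT|shared|PARENTS=|NOTE=second sub-terminal C variant, LAVA_C1 to C4/D
CGCTTGGAACGCCGCCCGCGAGTCGGGTCGGACGGCT
>C|5'|shared|PARENTS=|NOTE=5'-terminal C, LAVA_B2B
CCTTTGGATCGCCGCCCGCGAGTCGGGTCGGGCGGCC
>C|C2|shared|PARENTS=|NOTE=LAVA_C2-specific C
CGCTTGAATCGCCGCCCGCGCGTCGGGTTGGGCGGCC
>D|C2|LAVA|PARENTS=|NOTE=LAVA_C2-specific D
CGCTTGGATCGCCCAACGGGGGGACTCACGTCGGCCGCGT
>K|'|SVA|PARENTS=|NOTE=5'-most K of internal K_nGC' arrays
AGGAATGGTTATCATTTCCGGGCCGTCCGCCTGGTGGTCACCGGGGGAG
>L|'|SVA|PARENTS=|NOTE=second L of SVA_E LL'GC' arrays
GGGAATGGTGATCAGTTCCGGGCCGAGCGTCTGGTCGTCTCCCGGCGTAG
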