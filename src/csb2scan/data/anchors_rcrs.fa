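>upstream_flank G-rich strand 5' flank of the CSB 2 tract; reverse complement of rCRS 316-325
GGCCAGAAGC
>downstream_flank G-rich strand 3' flank of the CSB 2 tract; reverse complement of rCRS 294-302
TTTGGTGGA
>upstream_extension further 5' reference context; reverse complement of rCRS 326-340
GTGTTTAAGTGCTGT
>downstream_extension further 3' reference context; reverse complement of rCRS 279-293
AATTTTTTGTTATGA
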