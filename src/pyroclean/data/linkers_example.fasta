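>flx_linker example 454 GS FLX paired-end linker - verify against your chemistry before use
GTTGGAACCGAAAGGGTTTGAATTCAAACCCTTTCGGTTCCAAC
>titanium_linker example 454 Titanium paired-end linker - verify against your chemistry before use
TCGTATAACTTCGTATAATGTATGCTATACGAAGTTATTACG
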