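# synonym	official
FRAP1	MTOR
PYK2	PTK2B
FAK	PTK2
LGR7	RXFP1
CLECSF6	CLEC4A
IGF-1R	IGF1R
IRS-1	IRS1
GIT-1	GIT1
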