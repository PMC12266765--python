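locus	allele	status	disease
MT-ATP6	T8993G	Cfrm	NARP / Leigh syndrome
MT-ATP6	T8993C	Cfrm	NARP / Leigh syndrome
MT-TL1	A3243G	Cfrm	MELAS
MT-TK	A8344G	Cfrm	MERRF
MT-ND4	G11778A	Cfrm	LHON
MT-ND1	G3460A	Cfrm	LHON
MT-ND6	T14484C	Cfrm	LHON
MT-RNR1	A1555G	Cfrm	aminoglycoside-induced deafness
MT-TI	A4300G	Cfrm	maternally inherited cardiomyopathy
MT-ND5	G13513A	Cfrm	MELAS / Leigh overlap
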