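haplotype	rs3834466	rs28440105	rs10128556	rs968857
AI	GT	C	T	T
SEN	G	C	T	T
BEN	G	C	C	T
CAR	G	C	C	C
CAM	G	A	C	T
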