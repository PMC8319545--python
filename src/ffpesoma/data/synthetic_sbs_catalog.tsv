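Type	Subtype	SBS7a	SBS7b	SBS45	SBS52
C>A	A>A	0.0	0.0	0.05	0.03125
C>A	A>C	0.0	0.0	0.075	0.03125
C>A	A>G	0.0	0.0	0.025	0.03125
C>A	A>T	0.0	0.0	0.1	0.03125
C>A	C>A	0.0	0.0	0.05	0.03125
C>A	C>C	0.0	0.0	0.075	0.03125
C>A	C>G	0.0	0.0	0.025	0.03125
C>A	C>T	0.0	0.0	0.1	0.03125
C>A	G>A	0.0	0.0	0.05	0.03125
C>A	G>C	0.0	0.0	0.075	0.03125
C>A	G>G	0.0	0.0	0.025	0.03125
C>A	G>T	0.0	0.0	0.1	0.03125
C>A	T>A	0.0	0.0	0.05	0.03125
C>A	T>C	0.0	0.0	0.075	0.03125
C>A	T>G	0.0	0.0	0.025	0.03125
C>A	T>T	0.0	0.0	0.1	0.03125
C>G	A>A	0.0	0.0	0.0	0.0
C>G	A>C	0.0	0.0	0.0	0.0
C>G	A>G	0.0	0.0	0.0	0.0
C>G	A>T	0.0	0.0	0.0	0.0
C>G	C>A	0.0	0.0	0.0	0.0
C>G	C>C	0.0	0.0	0.0	0.0
C>G	C>G	0.0	0.0	0.0	0.0
C>G	C>T	0.0	0.0	0.0	0.0
C>G	G>A	0.0	0.0	0.0	0.0
C>G	G>C	0.0	0.0	0.0	0.0
C>G	G>G	0.0	0.0	0.0	0.0
C>G	G>T	0.0	0.0	0.0	0.0
C>G	T>A	0.0	0.0	0.0	0.0
C>G	T>C	0.0	0.0	0.0	0.0
C>G	T>G	0.0	0.0	0.0	0.0
C>G	T>T	0.0	0.0	0.0	0.0
C>T	A>A	0.0	0.0	0.0	0.0
C>T	A>C	0.0	0.0	0.0	0.0
C>T	A>G	0.0	0.0	0.0	0.0
C>T	A>T	0.0	0.0	0.0	0.0
C>T	C>A	0.0	0.2	0.0	0.0
C>T	C>C	0.0	0.3	0.0	0.0
C>T	C>G	0.0	0.1	0.0	0.0
C>T	C>T	0.0	0.4	0.0	0.0
C>T	G>A	0.0	0.0	0.0	0.0
C>T	G>C	0.0	0.0	0.0	0.0
C>T	G>G	0.0	0.0	0.0	0.0
C>T	G>T	0.0	0.0	0.0	0.0
C>T	T>A	0.2	0.0	0.0	0.0
C>T	T>C	0.3	0.0	0.0	0.0
C>T	T>G	0.1	0.0	0.0	0.0
C>T	T>T	0.4	0.0	0.0	0.0
T>A	A>A	0.0	0.0	0.0	0.0
T>A	A>C	0.0	0.0	0.0	0.0
T>A	A>G	0.0	0.0	0.0	0.0
T>A	A>T	0.0	0.0	0.0	0.0
T>A	C>A	0.0	0.0	0.0	0.0
T>A	C>C	0.0	0.0	0.0	0.0
T>A	C>G	0.0	0.0	0.0	0.0
T>A	C>T	0.0	0.0	0.0	0.0
T>A	G>A	0.0	0.0	0.0	0.0
T>A	G>C	0.0	0.0	0.0	0.0
T>A	G>G	0.0	0.0	0.0	0.0
T>A	G>T	0.0	0.0	0.0	0.0
T>A	T>A	0.0	0.0	0.0	0.0
T>A	T>C	0.0	0.0	0.0	0.0
T>A	T>G	0.0	0.0	0.0	0.0
T>A	T>T	0.0	0.0	0.0	0.0
T>C	A>A	0.0	0.0	0.0	0.03125
T>C	A>C	0.0	0.0	0.0	0.03125
T>C	A>G	0.0	0.0	0.0	0.03125
T>C	A>T	0.0	0.0	0.0	0.03125
T>C	C>A	0.0	0.0	0.0	0.03125
T>C	C>C	0.0	0.0	0.0	0.03125
T>C	C>G	0.0	0.0	0.0	0.03125
T>C	C>T	0.0	0.0	0.0	0.03125
T>C	G>A	0.0	0.0	0.0	0.03125
T>C	G>C	0.0	0.0	0.0	0.03125
T>C	G>G	0.0	0.0	0.0	0.03125
T>C	G>T	0.0	0.0	0.0	0.03125
T>C	T>A	0.0	0.0	0.0	0.03125
T>C	T>C	0.0	0.0	0.0	0.03125
T>C	T>G	0.0	0.0	0.0	0.03125
T>C	T>T	0.0	0.0	0.0	0.03125
T>G	A>A	0.0	0.0	0.0	0.0
T>G	A>C	0.0	0.0	0.0	0.0
T>G	A>G	0.0	0.0	0.0	0.0
T>G	A>T	0.0	0.0	0.0	0.0
T>G	C>A	0.0	0.0	0.0	0.0
T>G	C>C	0.0	0.0	0.0	0.0
T>G	C>G	0.0	0.0	0.0	0.0
T>G	C>T	0.0	0.0	0.0	0.0
T>G	G>A	0.0	0.0	0.0	0.0
T>G	G>C	0.0	0.0	0.0	0.0
T>G	G>G	0.0	0.0	0.0	0.0
T>G	G>T	0.0	0.0	0.0	0.0
T>G	T>A	0.0	0.0	0.0	0.0
T>G	T>C	0.0	0.0	0.0	0.0
T>G	T>G	0.0	0.0	0.0	0.0
T>G	T>T	0.0	0.0	0.0	0.0
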