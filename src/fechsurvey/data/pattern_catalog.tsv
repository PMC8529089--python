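name	pattern	description
consensus_2fe2s	C-X(1,11)-C-X(1,11)-C	consensus [2Fe-2S] coordination motif (three cysteines)
cx3cc	C-X(3)-C-C	partial motif: adjacent pair three residues after a cysteine
cx9cc	C-X(9)-C-C	partial motif: adjacent pair nine residues after a cysteine
exxnxr	E-X(2)-N-X-R	CAB-domain C-terminal motif (cyanobacteria)
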