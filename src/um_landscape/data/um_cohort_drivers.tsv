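sample	BAP1	EIF1AX	GNA11	GNAQ	PLCB4	SF3B1
00028-001-CL	p.D73Vfs*4		p.Q209L			p.R625C
00038-001-CL			p.Q209L
00061-001-CL	p.R699Qfs*6		p.Q209L
00085-001-CL	p.H224Qfs*14		p.Q209L
00099-001-CL			p.Q209L
141378RG-T						p.R625H
258	p.F170Lfs*13				p.D630Y	p.K666T
531		p.G8R	p.Q209L
533	p.G579Efs*63		p.Q209L
534			p.Q209L
535		splice		p.Q209P
537			p.Q209L
538		p.G6V	p.Q209L
539			p.Q209L
550	p.V346Sfs*51			p.Q209P
552	p.G41_54del			p.G48L
553			p.Q209L
554
556	Splice			p.Q209P
557		p.P2L		p.Q209P
C0622943-T			p.Q209L
ETB-0002-T	Splice			p.Q209P
J2217960PR-T				p.Q209P
K0111890AC-T				p.Q209P
MM1488-T
MM1551-T	p.Q684X				p.D630Y
MM1563-T
MM639-T	p.G128R		p.Q209L
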