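# mtDNA point variants of proband HZF001 relative to the rCRS (H-strand
# notation). Replacement dialect: ref-alt joined by a dash; an insertion is
# written as an extended alt (310 C-CC); a missense replacement carries the
# amino-acid change in parentheses. Blank gene cells continue the row above.
gene	position	replacement	crs	sample	previously_reported
D-loop	73	A-G	A	G	Yes
	194	C-T	C	T	Yes
	263	A-G	A	G	Yes
	310	C-CC	C	CC	Yes
	16093	T-C	T	C	Yes
	16223	C-T	C	T	Yes
	16362	T-C	T	C	Yes
	16519	T-C	T	C	Yes
MT-RNR1	750	A-G	A	G	Yes
	1382	A-C	A	C	Yes
	1438	A-G	A	G	Yes
MT-RNR2	2706	A-G	A	G	Yes
	3010	G-A	G	A	Yes
MT-ND2	4721	A-G	A	G	Yes
	4769	A-G	A	G	Yes
	4883	C-T	C	T	Yes
	5178	C-T	C	T	Yes
MT-TC	5802	T-C	T	C	No
MT-COX1	7028	C-T	C	T	Yes
	7076	A-G	A	G	Yes
MT-COX2	8020	G-A	G	A	Yes
MT-ATP8	8414	C-T( Leu17Phe)	C	T	Yes
MT-ATP6	8701	A-G(Thr59Ala)	A	G	Yes
	8830	C-A(Leu102Met)	C	A	Yes
	8860	A-G( Thr112Ala)	A	G	Yes
	8964	C-T	C	T	Yes
MT-COX3	9296	C-T	C	T	Yes
	9540	T-C	T	C	Yes
	9932	G-A	G	A	Yes
MT-ND3	10398	A-G(Thr114Ala)	A	G	Yes
	10400	C-T	C	T	Yes
MT-ND4	10873	T-C	T	C	Yes
	11719	G-A	G	A	Yes
MT-ND5	12705	C-T	C	T	Yes
	13748	A-G( Asn471Ser)	A	G	Yes
	13753	T-C(Ser473Pro)	T	C	Yes
	13754	C-T( Ser473Phe)	C	T	Yes
	13759	G-A(Ala475Thr)	G	A	Yes
	13775	C-T( Thr480Met)	C	T	Yes
	13776	A-G	A	G	Yes
MT-ND6	14668	C-T	C	T	Yes
MT-CYTB	14766	C-T( Thr7Ile)	C	T	Yes
	14783	T-C	T	C	Yes
	15043	G-A	G	A	Yes
	15236	A-G(Ile164Val)	A	G	Yes
	15301	G-A	G	A	Yes
	15326	A-G( Thr194Ala)	A	G	Yes
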