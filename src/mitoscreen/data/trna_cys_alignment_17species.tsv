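# Block-structured alignment of the mitochondrial tRNA-Cys gene from 17
# vertebrate species, in gene (tRNA 5'->3') orientation. One column per
# cloverleaf block; the #anchor row gives the canonical tRNA position of the
# first column of each block. Stem blocks are fixed-width across species;
# loop / variable-region blocks are left-aligned and may be ragged.
species	acceptor_stem_5p	link_8_9	d_stem_5p	d_loop	d_stem_3p	pos_26	anticodon_stem_5p	anticodon_loop	anticodon_stem_3p	variable_region	t_stem_5p	t_loop	t_stem_3p	acceptor_stem_3p	discriminator
#anchor	1	8	10	14	22	26	27	32	39	44	49	54	61	66	73
Cebus albifrons	AGCCCTG	AG	GTGA	ACTG	TCAT	G	TTGAA	CTGCAAA	TTCAA	AGAA	GCAGC	TTCAAT	GCTGC	CGGGGCT	T
Cercopithecus aethiops	AGCCCCG	AG	GTGA	TTT	TCAT	G	TTAAA	TTGCAAG	TTTAA	AGGA	GCAGT	TTTGAGTT	TCTGC	CGGGGCT	T
Colobus guereza	AGTCCCG	AG	GTGA	TTT	TCAT	G	TTGAA	TTGCAAA	TTCAA	AGGA	GCAGC	TTAAGACC	TCTGC	CGGGGCT	T
Gorilla gorilla	AGCTCCG	AG	GTGA	ATT	TCAT	A	TTGAA	TTGCAAA	TTCGA	AGAA	GCAGC	TTCAAA	CCTGC	CGGGGCT	T
Homo sapiens	AGCTCCG	AG	GTGA	TTT	TCAT	A	TTGAA	TTGCAAA	TTCGA	AGAA	GCAGC	TTCAAA	CCTGC	CGGGGCT	T
Hylobates lar	AGTCCCG	AA	GTGG	TTT	TCAC	G	TTGAA	TTGCAAA	TTCAA	AGGA	GCAGC	TTCAAT	CCTGC	CGGGGCT	T
Lemur catta	AGCCCTG	TA	GTGA	ATA	TCAC	G	TTGGA	TTGCAAA	TTCAA	AGAA	GCAGC	TTCAAT	TCTGC	CGGGGCT	T
Macaca mulatta	AGCCCCG	AG	GTGA	TTT	TCAT	G	TTGAA	TTGCAAG	TTCAA	AGGA	GCAGT	CTTAGAGTT	TCTGC	CGGGGCT	T
Macaca sylvanus	AGCTCCG	AG	GTGA	TTT	TCAT	G	TTGAA	TTGCAAA	TTCAA	AGGA	GCAGT	TCCAAAGTT	TCTGC	CGGGGCT	T
Nycticebus coucang	GGCCTCG	AG	GTGA	TAAA	TCAT	A	TTGAA	TTGCAAA	TTCAA	AGGA	GCAGC	TTCAAT	TCTGC	CGGGGCT	T
Pan paniscus	AGCTCTG	AG	GTGA	TTT	TCAT	A	TTGAA	TTGCAAA	TTCAA	AGAA	GCAGC	TTCAAA	CCTGC	CGGGGCT	T
Pan troglodytes	AGCTCTG	AG	GTGA	TTT	TCAT	A	TTGAA	TTGCAAA	TTCGA	AGAA	GCAGC	TTCAAA	CCTGC	CGGGGCT	T
Papio hamadryas	AGCCCCG	AG	GTGA	TTT	TCAC	A	TTGAA	TTGCAAG	TTCGA	AGGA	GCAGC	TTTAAGTT	TCTGC	CGGGGCT	T
Pongo pygmaeus	AGCCCTG	AG	GTGA	TTG	TCAT	G	TTGAA	TTGCAAA	TTCGA	AGGA	GCAGC	TTTAAGG	CCTGC	CGGGGCT	T
Pongo pygmaeus abelii	AGCCCCG	AG	GTGA	TTG	TCAT	G	TTGAA	TTGCAAA	TTCGA	AGGA	GCAGC	TTTAAGG	CCTGC	CGGGGCT	T
Tarsius bancanus	AGTCCTG	AA	GTGA	ATA	TCAT	A	TTGAA	TTGCAAA	TTCAA	AGAA	GCAGC	TTCAAT	TCTGC	CGGGACT	T
Trachypithecus obscurus	AGCCCCG	AG	GTGG	TTT	TCAT	G	TTGAA	TTGCAAA	TTCAA	AGGA	GCAGT	TAGATT	TCTGC	CGGGGCT	T
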