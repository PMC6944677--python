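# DEMO-ONLY three-generation pedigree (the published pedigree figure is not
# machine readable; this fixture encodes a 7-member matriline with 3 affected).
# mother '-' = founder or married-in; affected/carrier are 0/1 flags.
id	mother	affected	carrier
I-1	-	0	0
I-2	-	0	1
II-1	-	0	0
II-2	I-2	1	1
II-3	-	0	0
II-4	I-2	1	1
II-6	I-2	0	1
III-1	II-2	1	1
III-2	II-4	0	1
III-3	II-4	0	1
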