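# holosim-genome v1
# primitive cell-cycle wiring: 5 core regulator types (0..4) in a cyclic
# activation chain with three inhibitory binding sites; in the deterministic
# binding limit the core dynamics have a single non-trivial limit cycle
# visiting the four stage signatures G1 -> S -> G2 -> M with period 4.
index	kind	type_id	threshold	weight
0	BS	3		1
1	REG	0	1
2	BS	4		1
3	BS	2		-2
4	REG	1	1
5	BS	1		1
6	BS	4		1
7	BS	3		-2
8	REG	2	1
9	BS	2		1
10	REG	3	1
11	BS	0		1
12	BS	4		-2
13	REG	4	1
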