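# holosim-stage-table v1
# default mapping from 5-bit core-regulator activity patterns to cell-cycle
# stages; a core type counts as "on" when at least one copy of a gene of
# that type is active.
stage	t0	t1	t2	t3	t4
G1	1	0	0	0	1
S	0	1	1	0	0
G2	0	0	1	1	0
M	1	0	0	1	0
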