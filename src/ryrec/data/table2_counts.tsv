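location	assembly_coord	progeny	co	nco
endogenous	3R:8859889	3710000	112	53
6E	X:6845474	943000	6	10
20C	X:22221488	903500	10	7
2A	X:1346142	960600	0	0
102D	4:1008975	1285800	0	0
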