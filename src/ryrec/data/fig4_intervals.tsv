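location	interval	genetic_mu	physical_mb
endogenous	kar–cv-c	2.4	1.75
2A	su(wa)–pn	NA	1.16
6E	rux–cm	5	1.6
20C	mal–su(f)	1.1	2.2
102D	chr4-euchromatin	NA	1.35
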