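position	ry_plus	ry606N	ry609N	role	note
-3149	GTAC	-	GTAC	flanking	Destroys KpnI site for flanking marker
-2914	G	G	C	silent	Destroys PstI site
-710	C	A	C	silent	From ry606 chromosome
-679	A	G	A	silent	From ry606 chromosome
-527	G	T	G	silent	From ry606 chromosome
-468	G	A	G	selected	ry606 mutation
-332	T	G	T	silent	From ry606 chromosome
-323	T	C	T	silent	From ry606 chromosome
-320	A	C	A	silent	From ry606 chromosome
73	G	T	G	silent	From ry606 chromosome
239	C	T	C	silent	From ry606 chromosome
355	T	A	T	silent	From ry606 chromosome
449	T	C	T	silent	From ry606 chromosome
467	C	T	C	silent	From ry606 chromosome, creates AgeI site
1103	C	C	G	silent	Destroys PstI site (with +1106)
1106	C	C	T	silent	Destroys PstI site (with +1103)
2950	A	A	G	silent	Destroys BamHI site
3358	C	C	G	silent	Destroys SphI site
3506	G	G	A	selected	ry609 mutation
3511	A	A	T	silent	Creates BglII site (with +3506)
3610	C	C	A	silent	Creates EcoRI site
3735	A	A	C	silent	Creates BamHI site
4163	-	-	GATATCGAATT	silent	Inserts EcoRV and EcoRI sites
4169	C	C	G	silent	Destroys NheI site
6998	C	C	G	flanking	Destroys AgeI site for flanking marker
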