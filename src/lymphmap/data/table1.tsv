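Location	Type	Ref	Allele	Gene	Exon Number	Consequence	A.A.Change
25205559^25205560	Ins	-	T	MYC	3/3	3 prime UTR	-
26907214	SNP	A	G	GSDMC	1/12	missense	H/R
28304328	SNP	G	A	LDH	1/1	missense	D/N
28304341	SNP	T	C	LDH	1/1	missense	V/A
29249168	SNP	C	T	TMEM71	1/11	5 prime UTR	-
29681948	SNP	G	A	WISP1	4/4	3 prime UTR	-
29682320	SNP	A	T	WISP1	4/4	3 prime UTR	-
29689113	SNV	A	T	NDRG1	16/16	3 prime UTR	-
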