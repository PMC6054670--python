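##fileformat=VCFv4.2
##contig=<ID=chrA,length=100000>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect class">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	TUMOR	NORMAL
chrA	1000	.	A	T	.	.	GENE=g01;EFFECT=missense	AD	40,15	60,0
chrA	2000	.	C	G	.	.	GENE=g02;EFFECT=missense	AD	50,9	60,0
chrA	3000	.	G	A	.	.	GENE=g03;EFFECT=nonsense	AD	40,20	57,3
chrA	4000	.	T	C	.	.	GENE=g04;EFFECT=missense	AD	30,19	60,0
chrA	5000	.	A	G	.	.	GENE=g05;EFFECT=splice	AD	60,20	49,0
chrA	50500	.	C	T	.	.	GENE=g06;EFFECT=missense	AD	40,20	60,0
chrA	7000	.	G	C	.	.	GENE=g07;EFFECT=frameshift	AD	40,10	48,2
chrA	8000	.	T	A	.	.	GENE=g08;EFFECT=missense	AD	40,9	60,0
chrA	9000	.	A	C	.	.	GENE=g09;EFFECT=missense	AD	60,20	47,3
chrA	10000	.	C	A	.	.	GENE=g10;EFFECT=nonsense	AD	90,30	48,2
chrA	50001	.	G	T	.	.	GENE=g11;EFFECT=missense	AD	60,25	70,0
chrA	53001	.	T	G	.	.	GENE=g12;EFFECT=missense	AD	60,25	70,0
chrA	13000	.	A	T	.	.	GENE=g13;EFFECT=other	AD	20,5	30,3
chrA	14000	.	C	G	.	.	GENE=g14;EFFECT=missense	AD	100,80	120,1
chrA	15000	.	G	A	.	.	GENE=g15;EFFECT=missense	AD	80,0	90,0
chrA	16000	.	T	C	.	.	GENE=g16;EFFECT=missense	AD	60,30	40,20
chrA	17000	.	A	G	.	.	GENE=g17;EFFECT=splice	AD	45,12	55,1
chrA	18000	.	C	T	.	.	GENE=g18;EFFECT=missense	AD	25,24	60,0
chrA	50000	.	G	C	.	.	GENE=g19;EFFECT=missense	AD	70,20	80,0
chrA	53000	.	T	A	.	.	GENE=g20;EFFECT=missense	AD	70,20	80,0
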