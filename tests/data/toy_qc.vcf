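##fileformat=VCFv4.2
##source=cnvselscan-test-fixture
##contig=<ID=chr1,length=40000000>
##ALT=<ID=DEL,Description="DEL">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	HL01	HL02	HL03	HL04	HL05	LL01	LL02	LL03	LL04	LL05
chr1	100000	long1	N	<DEL>	.	.	SVTYPE=DEL;SVLEN=-10000001;END=10100000	GT	0/0	0/0	0/0	0/0	0/0	0/1	0/1	0/1	1/1	1/1
chr1	12000000	long2	N	<DEL>	.	.	SVTYPE=DEL;SVLEN=-15000000;END=26999999	GT	0/0	0/0	0/0	0/0	0/0	0/0	0/1	0/1	0/1	0/1
chr1	500000	allhet	N	<DEL>	.	.	SVTYPE=DEL;SVLEN=-2000;END=501999	GT	0/1	0/1	0/1	0/1	0/1	0/1	0/1	0/1	0/1	0/1
chr1	800000	miss1	N	<DEL>	.	.	SVTYPE=DEL;SVLEN=-1500;END=801499	GT	./.	./.	./.	0/0	0/0	0/0	0/0	0/1	0/1	1/1
chr1	1200000	miss2	N	<DEL>	.	.	SVTYPE=DEL;SVLEN=-1800;END=1201799	GT	./.	./.	./.	./.	0/0	0/0	0/0	0/1	0/1	1/1
chr1	1500000	mono_ref	N	<DEL>	.	.	SVTYPE=DEL;SVLEN=-3000;END=1502999	GT	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0
chr1	1800000	mono_alt	N	<DEL>	.	.	SVTYPE=DEL;SVLEN=-2500;END=1802499	GT	1/1	1/1	1/1	1/1	1/1	1/1	1/1	1/1	1/1	1/1
chr1	2000000	clean1	N	<DEL>	.	.	SVTYPE=DEL;SVLEN=-4000;END=2003999	GT	./.	./.	0/0	0/0	0/0	0/0	0/0	0/1	0/1	1/1
chr1	2300000	clean2	N	<DEL>	.	.	SVTYPE=DEL;SVLEN=-1200;END=2301199	GT	0/0	0/0	0/0	0/0	0/0	0/0	0/1	0/1	0/1	1/1
chr1	2600000	clean3	N	<DEL>	.	.	SVTYPE=DEL;SVLEN=-5000;END=2604999	GT	0/0	0/0	0/0	0/1	0/1	0/1	0/1	1/1	1/1	1/1
chr1	3000000	clean4	N	<DEL>	.	.	SVTYPE=DEL;SVLEN=-2200;END=3002199	GT	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/1	1/1
chr1	3400000	clean5	N	<DEL>	.	.	SVTYPE=DEL;SVLEN=-1600;END=3401599	GT	./.	0/0	0/0	0/0	0/0	0/0	0/1	0/1	0/1	1/1
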