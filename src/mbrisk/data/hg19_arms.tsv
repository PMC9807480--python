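chrom	arm	start	end	acrocentric
chr1	p	0	121535434	0
chr1	q	124535434	249250621	0
chr2	p	0	92326171	0
chr2	q	95326171	243199373	0
chr3	p	0	90504854	0
chr3	q	93504854	198022430	0
chr4	p	0	49660117	0
chr4	q	52660117	191154276	0
chr5	p	0	46405641	0
chr5	q	49405641	180915260	0
chr6	p	0	58830166	0
chr6	q	61830166	171115067	0
chr7	p	0	58054331	0
chr7	q	61054331	159138663	0
chr8	p	0	43838887	0
chr8	q	46838887	146364022	0
chr9	p	0	47367679	0
chr9	q	50367679	141213431	0
chr10	p	0	39254935	0
chr10	q	42254935	135534747	0
chr11	p	0	51644205	0
chr11	q	54644205	135006516	0
chr12	p	0	34856694	0
chr12	q	37856694	133851895	0
chr13	p	0	16000000	1
chr13	q	19000000	115169878	0
chr14	p	0	16000000	1
chr14	q	19000000	107349540	0
chr15	p	0	17000000	1
chr15	q	20000000	102531392	0
chr16	p	0	35335801	0
chr16	q	38335801	90354753	0
chr17	p	0	22263006	0
chr17	q	25263006	81195210	0
chr18	p	0	15460898	0
chr18	q	18460898	78077248	0
chr19	p	0	24681782	0
chr19	q	27681782	59128983	0
chr20	p	0	26369569	0
chr20	q	29369569	63025520	0
chr21	p	0	11288129	1
chr21	q	14288129	48129895	0
chr22	p	0	13000000	1
chr22	q	16000000	51304566	0
chrX	p	0	58632012	0
chrX	q	61632012	155270560	0
chrY	p	0	10104553	0
chrY	q	13104553	59373566	0
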