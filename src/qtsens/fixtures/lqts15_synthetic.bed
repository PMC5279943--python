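# Synthetic gene intervals for the 15-gene LQTS panel (0-based, half-open).
# Coordinates are invented for testing interval restriction; they are NOT
# genomic annotations. One toy contig per gene, 100 kb apart.
chr7	100000	250000	AKAP9
chr4	400000	560000	ANK2
chr12	700000	1340000	CACNA1C
chr14	1500000	1510000	CALM1
chr2	1700000	1716000	CALM2
chr3	1900000	1913000	CAV3
chr21	2100000	2107000	KCNE1
chr21	2300000	2307000	KCNE2
chr7	2500000	2533000	KCNH2
chr17	2700000	2711000	KCNJ2
chr11	2900000	2930000	KCNJ5
chr11	3100000	3504000	KCNQ1
chr11	3700000	3720000	SCN4B
chr3	3900000	4001000	SCN5A
chr20	4200000	4236000	SNTA1
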