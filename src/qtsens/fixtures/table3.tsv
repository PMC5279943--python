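# Significantly imbalanced SNPs over the LQTS gene panel: per-group observed
# minor-allele frequencies (fractions) and the published two-group p-value.
# Rows that shared one printed line (identical observed MAFs and p) are expanded
# to one row per rs id. p_printed is carried as an annotation, not recomputed.
gene	snp_id	anticipated_maf	maf_low	maf_high	p_printed
ANK2	rs17045935	0.068	0.00	0.222	0.03
ANK2	rs62314901	0.400	0.5625	0.278	0.037
ANK2	rs17676256	0.102	0.125	0.389	0.03
ANK2	rs9670993	0.081	0.25	0.444	0.027
ANK2	rs4834321	0.469	0.375	0.556	0.02
ANK2	rs35308370	0.483	0.25	0.667	0.025
ANK2	rs931838	0.425	0.3125	0.667	0.048
SCN5A	rs7375123	0.192	0.4375	0.112	0.007
SCN5A	rs12491987	0.076	0.00	0.222	0.03
SCN5A	rs9871385	0.341	0.0625	0.333	0.02
SCN5A	rs9818148	0.192	0.5625	0.167	0.049
KCNQ1	rs4255520	0.155	0.1875	0.00	0.043
KCNQ1	rs151288	0.327	0.00	0.222	0.031
KCNQ1	rs718579	0.398	0.125	0.278	0.034
KCNQ1	rs11022996	0.412	0.125	0.278	0.034
KCNQ1	rs151212	0.408	0.50	0.333	0.05
CACNA1C	rs3794299	0.124	0.1875	0.00	0.043
CACNA1C	rs4765661	0.158	0.3125	0.056	0.027
CACNA1C	rs2238018	0.173	0.3125	0.056	0.027
CALM1	rs3814843	0.018	0.00	0.222	0.031
CALM1	rs2300502	0.075	0.0625	0.333	0.023
KCNE2	rs28409368	0.308	0.1875	0.389	0.0239
KCNH2	rs2072411	0.375	0.1875	0.444	0.027
KCNH2	rs3778873	0.158	0.062	0.444	0.02
KCNJ5	rs7924416	0.246	0.00	0.278	0.013
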