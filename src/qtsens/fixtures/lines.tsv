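# iPSC line panel: group membership, karyotype and E4031 responsiveness.
# gender is derived from the sex chromosomes of the karyotype (46,XX -> F; 46,XY -> M).
# karyotype_ok is False for the line carrying the t(1;16) translocation.
line_id	group	karyotype	gender	karyotype_ok	e4031_responder
P11007	low	46,XY	M	True	True
P11008	high	46,XX	F	True	True
P11009	low	46,XY	M	True	True
P11013	high	46,XX	F	True	True
P11014	low	46,XX	F	True	True
P11015	high	46,XX	F	True	True
P11018	high	46,XX	F	True	True
P11019	high	46,XY	M	True	True
P11020	low	46,XY	M	True	True
P11021	high	46,XX	F	True	False
P11023	high	46,XX	F	True	False
P11024	high	46,XX	F	True	True
P11026	low	46,XY	M	True	True
P11028	low	46,XY	M	True	True
P11029	high	46,XX	F	True	True
P11030	low	46,XX,t(1;16)	F	False	True
P11031	low	46,XY	M	True	True
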