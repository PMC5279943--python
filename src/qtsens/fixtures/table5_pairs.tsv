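# Same-gender pairs: each pair joins one high-sensitivity and one
# low-sensitivity line of the same gender (6 male pairs, 16 female pairs).
gender	high_line	low_line
M	P11019	P11028
M	P11019	P11026
M	P11019	P11020
M	P11019	P11009
M	P11019	P11031
M	P11019	P11007
F	P11008	P11030
F	P11015	P11030
F	P11013	P11030
F	P11029	P11030
F	P11018	P11030
F	P11024	P11030
F	P11023	P11030
F	P11021	P11030
F	P11008	P11014
F	P11015	P11014
F	P11013	P11014
F	P11029	P11014
F	P11018	P11014
F	P11024	P11014
F	P11023	P11014
F	P11021	P11014
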