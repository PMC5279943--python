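AKAP9
ANK2
CACNA1C
CALM1
CALM2
CAV3
KCNE1
KCNE2
KCNH2
KCNJ2
KCNJ5
KCNQ1
SCN4B
SCN5A
SNTA1
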