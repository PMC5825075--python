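condition,weight,codes
myocardial_infarction,1,I21;I22;I252
congestive_heart_failure,1,I50;I110
peripheral_vascular_disease,1,I70;I71;I731;I738;I739
cerebrovascular_disease,1,I60;I61;I62;I63;I64;I65;I66;I67;I69;G45;G46
rheumatic_disease,1,M05;M06;M315;M32;M33;M34
peptic_ulcer_disease,1,K25;K26;K27;K28
liver_disease,1,B18;K70;K71;K73;K74
diabetes,1,E10;E11;E13;E14
hemiplegia_paraplegia,2,G81;G82
renal_disease,2,N18;N19;I120;I131
any_cancer,2,C
aids_hiv,6,B20;B21;B22;B24
dementia,1,F00;F01;F02;F03;G30;G31
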