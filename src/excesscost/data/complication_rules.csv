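name,inclusion_codes,exclusion_codes,exclusion_scope
urinary_tract_infection,N390;T835,N10;N11;N12;N13;N20;N21;N23;N30;N31;N32;N34;N35;N36;N37,principal_only
pressure_injury,L89,G81;G82,principal_or_additional
pneumonia,J12;J13;J14;J15;J16;J17;J18,J69;J80;J95,principal_or_additional
delirium,F05,F10;G92,principal_or_additional
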