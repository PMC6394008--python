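patient_id,sex,birth_date,death_date
P00000,female,1922-04-13,2016-03-11
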