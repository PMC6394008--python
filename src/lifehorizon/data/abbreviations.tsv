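# abbreviation -> expansion (lower-case, tab-separated)
p	patient
pt	patient
pat	patient
med	medicatie
ca	carcinoom
vg	voorgeschiedenis
lab	laboratorium
tel	telefonisch
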