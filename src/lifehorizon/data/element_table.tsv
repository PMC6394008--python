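# ICPC numeric component ranges -> thematic consultation element
# range(lo-hi, inclusive)<TAB>element label
1-29	symptom or complaint
30-49	standard procedure
50-59	treatment or medication procedure
60-69	test result or administrative
70-99	diagnosis or disease
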