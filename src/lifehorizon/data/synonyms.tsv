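# variant -> canonical concept (lower-case, tab-separated)
oesophagus	slokdarm
esophagus	slokdarm
oesofagus	slokdarm
tumor	carcinoom
gezwel	carcinoom
maagzuur	reflux
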