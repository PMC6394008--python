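# function words excluded from keyword ranking (one per line)
de
het
een
en
of
in
op
te
bij
van
met
voor
naar
is
zijn
heeft
wordt
dat
dit
er
niet
geen
ook
nog
al
the
a
an
and
of
to
is
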