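# valid word forms for spelling correction (one per line)
patient
patienten
medicatie
carcinoom
voorgeschiedenis
laboratorium
telefonisch
slokdarm
reflux
klachten
controle
bloeddruk
overleg
huisarts
gesprek
pijn
moe
onderzoek
uitslag
stabiel
vervolg
thuis
familie
zorg
recept
verwijzing
besproken
afspraak
conditie
eetlust
gewicht
benauwd
slapen
lopen
vallen
geheugen
palliatief
hospice
terminaal
heeft
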