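# Terms added to abstracts by publishers for copyright/boilerplate reasons.
# Configurable; extend for the publishers present in a given corpus.
copyright
rights
reserved
elsevier
springer
wiley
blackwell
verlag
ltd
inc
bv
gmbh
publishing
publisher
publishers
press
abstract
doi
crossref
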