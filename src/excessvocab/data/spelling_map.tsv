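colour	color
colours	colors
behaviour	behavior
behaviours	behaviors
analyse	analyze
analysed	analyzed
analysing	analyzing
modelling	modeling
modelled	modeled
labelled	labeled
tumour	tumor
tumours	tumors
centre	center
fibre	fiber
utilise	utilize
utilised	utilized
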