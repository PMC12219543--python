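delves	delve
delving	delve
delved	delve
underscores	underscore
underscored	underscore
underscoring	underscore
showcasing	showcase
showcases	showcase
showcased	showcase
masks	mask
chatbots	chatbot
circrnas	circrna
insights	insight
findings	finding
exhibited	exhibit
enhancing	enhance
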