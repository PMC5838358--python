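term	variants	present_in_corpus
thc		1
cannabis		1
marijuana	marijuanas	1
hemp		1
medicinal		1
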