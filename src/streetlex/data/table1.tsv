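condition	threshold	recall	precision
ganja	0.46	0.547	0.144
weed	0.49	0.453	0.111
union	0.53	0.396	0.146
simple_mean	0.50	0.490	0.122
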