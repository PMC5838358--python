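canonical	variants
gas	gass,gasss,gassss
reefer	reefa
tooka	tookah
moonrock	moonrocks
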