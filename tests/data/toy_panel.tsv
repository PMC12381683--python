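HL01	HL
HL02	HL
HL03	HL
HL04	HL
HL05	HL
LL01	LL
LL02	LL
LL03	LL
LL04	LL
LL05	LL
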