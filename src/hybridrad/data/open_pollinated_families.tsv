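species	mother	n_seedlings
ilex	E28	82
ilex	E31	84
ilex	E41	81
ilex	E96	93
suber	A05	71
suber	A07	94
suber	A09	101
suber	A10	103
hybrid	FS08	12
hybrid	FS14	19
hybrid	FS16	47
hybrid	FS17	26
hybrid	FS18	16
hybrid	FS19	57
hybrid	FS20	30
hybrid	FS21	5
hybrid	FS22	68
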