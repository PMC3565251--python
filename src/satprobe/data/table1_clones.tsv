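BAC	Chr.	Band	Start (bp)	End (bp)	Insert (bp)	BAC End Sequence Accession Number
RP11-242E13	Y	q12	multiple	multiple	98295	AC068123
RP11-348G24	X	p11.1	58,356,061	58,564,667	208607	AQ528470, AQ528473
RP11-88G23	16	q11.2	46,385,822	46,412,445	26624	AQ285754, AQ285753
RP11-246K16	16	q11.2	46,385,808	46,412,485	26678	AQ478385, AQ478388
RP11-416F8	16	q11.2	46,385,808	46,412,485	26678	AQ551230, AQ661227
RP11-486E19	16	q11.2	46,385,921	46,412,470	26550	AQ629869, AQ629871
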