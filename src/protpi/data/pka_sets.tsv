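# Named pKa scales for protein ionizable groups.
# columns: set	group	pka	polarity
# group is a one-letter residue code or the terminal group n_term / c_term.
set	group	pka	polarity
ipc_protein	n_term	9.094	basic
ipc_protein	c_term	2.869	acidic
ipc_protein	C	7.555	acidic
ipc_protein	D	3.872	acidic
ipc_protein	E	4.412	acidic
ipc_protein	H	5.637	basic
ipc_protein	K	9.052	basic
ipc_protein	R	11.84	basic
ipc_protein	Y	10.85	acidic
emboss	n_term	8.6	basic
emboss	c_term	3.6	acidic
emboss	C	8.5	acidic
emboss	D	3.9	acidic
emboss	E	4.1	acidic
emboss	H	6.5	basic
emboss	K	10.8	basic
emboss	R	12.5	basic
emboss	Y	10.1	acidic
sillero	n_term	9.6	basic
sillero	c_term	3.2	acidic
sillero	C	9.0	acidic
sillero	D	4.0	acidic
sillero	E	4.5	acidic
sillero	H	6.4	basic
sillero	K	10.4	basic
sillero	R	12.0	basic
sillero	Y	10.0	acidic
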