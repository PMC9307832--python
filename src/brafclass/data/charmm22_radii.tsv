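kind	key	radius	charmm_type
name	N	1.8500	NH1
name	CA	2.2750	CT1
name	C	2.0000	C
name	O	1.7000	O
name	OXT	1.7000	OC
name	CB	2.1750	CT2
name	SG	1.9750	SM
name	SD	1.9750	SM
name	OG	1.7700	OH1
name	OG1	1.7700	OH1
name	OH	1.7700	OH1
name	OD1	1.7000	OC
name	OD2	1.7000	OC
name	OE1	1.7000	OC
name	OE2	1.7000	OC
name	NZ	1.8500	NH3
name	NE	1.8500	NC2
name	NH1	1.8500	NC2
name	NH2	1.8500	NC2
name	ND1	1.8500	NR1
name	NE2	1.8500	NR2
name	ND2	1.8500	NH2
name	NE1	1.8500	NY
name	HA2	1.3200	HB
name	HA3	1.3200	HB
name	HA1	1.3200	HB
element	C	2.0600	CT3
element	N	1.8500	NH1
element	O	1.7000	O
element	S	2.0000	S
element	H	1.3200	HA
element	P	2.1500	P
element	MG	1.1850	MG
element	F	1.6300	F1
element	CL	1.9100	CLA
element	ZN	1.0900	ZN
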