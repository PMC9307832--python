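position	wt	mt	label
459	V	L	III
464	G	V	II
464	G	E	II
464	G	R	II
466	G	V	III
466	G	E	III
466	G	A	III
466	G	R	III
467	S	L	III
467	S	A	III
469	G	A	II
469	G	V	II
469	G	R	II
469	G	S	II
469	G	E	III
483	K	M	III
485	L	F	II
488	T	P	III
490	P	S	II
497	A	V	II
504	V	E	II
505	L	H	II
508	T	I	II
516	F	L	II
525	L	F	II
531	W	C	II
533	E	K	II
549	E	K	III
581	N	S	III
581	N	I	III
581	N	T	III
586	E	K	III
594	D	N	III
594	D	G	III
594	D	A	III
594	D	H	III
594	D	E	III
595	F	L	III
596	G	D	III
596	G	R	III
596	G	V	III
597	L	Q	II
597	L	V	II
597	L	R	II
597	L	S	II
599	T	I	II
601	K	E	II
601	K	N	II
601	K	T	II
601	K	Q	II
605	S	N	III
609	Q	H	III
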