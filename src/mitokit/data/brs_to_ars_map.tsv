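type	target_pos	target_base	source_pos	source_base
deletion	222	C	.	.
deletion	589	C	.	.
substitution	364	G	363	C
substitution	2538	A	2536	C
substitution	3345	G	3343	C
substitution	3387	C	3385	T
substitution	3541	A	3539	G
substitution	4321	C	4319	T
substitution	8190	C	8188	T
substitution	8712	T	8710	C
substitution	9684	C	9682	G
substitution	12167	C	12165	T
substitution	13312	C	13310	A
substitution	15637	T	15635	C
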