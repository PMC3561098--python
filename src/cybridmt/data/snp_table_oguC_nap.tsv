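gene	cds_pos	ref	alt	aa_pos	ref_aa	alt_aa	effect	snp_type
nad1	571	C	T	191	L	F	N	transition
nad2	367	T	C	123	C	R	N	transition
nad3	265	T	C	.	.	.	S	transition
nad4	77	C	T	26	P	L	N	transition
nad4	1205	C	T	402	P	L	N	transition
nad7	1079	T	C	360	F	S	N	transition
cox1	109	C	T	.	.	.	S	transition
cox1	111	T	A	.	.	.	S	transversion
cox1	786	T	G	.	.	.	S	transversion
cox2-1	379	T	C	127	W	R	N	transition
ccmB	353	G	A	.	.	.	N	transition
ccmC	126	A	G	.	.	.	S	transition
ccmC	155	G	A	52	R	H	N	transition
ccmC	338	G	A	113	R	K	N	transition
ccmC	351	G	A	.	.	.	S	transition
ccmC	476	C	A	.	.	.	S	transversion
ccmC	533	G	A	178	G	A	N	transition
ccmC	551	G	A	184	G	D	N	transition
ccmFC	283	G	A	95	E	K	N	transition
ccmFN1	361	T	A	121	F	I	N	transversion
ccmFN1	1000	C	T	334	L	F	N	transition
ccmFN2	380	C	T	127	L	S	N	transition
atp1	987	T	C	.	.	.	S	transition
atp4	176	C	T	59	A	V	N	transition
atp8	370	A	C	124	L	I	N	transversion
atp8	448	T	C	150	A	V	N	transition
atp9	64	A	G	22	I	V	N	transition
rps3	1254	A	C	.	.	.	S	transversion
rps3	1320	A	C	.	.	.	S	transversion
rps4	189	T	G	.	.	.	S	transversion
rps4	776	C	T	259	S	F	N	transition
rps12	12	T	G	4	F	L	N	transversion
rps12	336	A	C	112	R	S	N	transversion
rps12	345	A	C	.	.	.	S	transversion
rpl2	464	G	A	155	G	D	N	transition
rpl2	840	C	T	.	.	.	S	transition
rpl2	1004	C	T	335	S	L	N	transition
rpl5	515	T	C	172	L	P	N	transition
rpl16	506	C	T	169	P	L	N	transition
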