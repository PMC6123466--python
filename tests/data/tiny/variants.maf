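Hugo_Symbol	Chromosome	Start_Position	Reference_Allele	Tumor_Seq_Allele2	Variant_Classification	Variant_Type	Tumor_Sample_Barcode	t_ref_count	t_alt_count	Protein_Change
PIK3CA	1	1001425	T	C	Splice_Site	SNP	S0000	150	74	X476_splice
PIK3CA	1	1001851	C	A	Missense_Mutation	SNP	S0002	90	48	Q618E
PIK3CA	1	1000993	AGCT	A	In_Frame_Del	DEL	S0003	117	38	A332del
PIK3CA	1	1003015	G	T	Silent	SNP	S0004	17	10	E1006E
PIK3CA	1	1002226	AT	A	Frame_Shift_Del	DEL	S0006	140	119	H743fs
PIK3CA	1	1003039	G	C	Missense_Mutation	SNP	S0008	62	29	Y1014Q
TP53	2	2000033	A	T	Missense_Mutation	SNP	S0004	27	20	L12R
TP53	2	2000144	C	T	Nonsense_Mutation	SNP	S0008	54	22	Y49*
TP53	2	2000369	G	T	Missense_Mutation	SNP	S0010	142	93	C124P
MAP3K1	3	3003000	T	A	Nonsense_Mutation	SNP	S0000	52	31	N1001*
MAP3K1	3	3001458	C	G	Nonsense_Mutation	SNP	S0009	159	51	E487*
TP53	2	2000931	A	T	Silent	SNP	S0000	80	54	P311P
MAP3K1	3	3003949	G	A	Missense_Mutation	SNP	S0002	17	20	T1317N
MAP3K1	3	3000058	G	C	Missense_Mutation	SNP	S0003	100	143	T20D
TP53	2	2000124	G	A	Missense_Mutation	SNP	S0003	72	88	I42H
MAP3K1	3	3000058	G	C	Missense_Mutation	SNP	S0005	81	85	T20D
MAP3K1	3	3003949	G	A	Missense_Mutation	SNP	S0006	50	67	T1317N
TP53	2	2000124	G	A	Missense_Mutation	SNP	S0006	61	42	I42H
TP53	2	2000835	C	G	Missense_Mutation	SNP	S0008	31	29	E279K
MAP3K1	3	3000058	G	C	Missense_Mutation	SNP	S0009	197	180	T20D
MAP3K1	3	3000058	G	C	Missense_Mutation	SNP	S0010	77	44	T20D
TP53	2	2000124	G	A	Missense_Mutation	SNP	S0010	34	37	I42H
MAP3K1	3	3000058	G	C	Missense_Mutation	SNP	S0011	36	64	T20D
MAP3K1	3	3002891	A	G	Missense_Mutation	SNP	S0002	143	1	W964A
MAP3K1	3	3002891	A	G	Missense_Mutation	SNP	S0003	260	25	W964A
MAP3K1	3	3002891	A	G	Missense_Mutation	SNP	S0004	15	3	W964A
MAP3K1	3	3002891	A	G	Missense_Mutation	SNP	S0006	111	5	W964A
MAP3K1	3	3004340	C	T	Missense_Mutation	SNP	S0000	121	3	G1447M
MAP3K1	3	3004340	C	T	Missense_Mutation	SNP	S0002	141	7	G1447M
MAP3K1	3	3004340	C	T	Missense_Mutation	SNP	S0003	49	3	G1447M
MAP3K1	3	3004340	C	T	Missense_Mutation	SNP	S0005	80	5	G1447M
MAP3K1	3	3004340	C	T	Missense_Mutation	SNP	S0007	105	7	G1447M
MAP3K1	3	3004340	C	T	Missense_Mutation	SNP	S0009	72	1	G1447M
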