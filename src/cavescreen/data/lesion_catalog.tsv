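gene	kind	cdna_start	cdna_end	sequence	exon_ordinal	exon_count	cdna_length	strand	carriers	reference_carries
ghrb	insertion	1423	1425	TGT	7	7	1650	+	Pachon,Tinaja	yes
mia3	insertion	2013	2018	GATGCC	4	27	5667	+	Pachon,Tinaja	yes
mki67	insertion	1957	1992	CCCAAAACCCCTTCACCATCCTCATGCCCAGCAATG	9	16	6750	-	Pachon,Tinaja	yes
mki67	deletion	2154	2156	TTG	9	16	6750	-	Pachon,Tinaja	yes
mlf1	insertion	247	258	ATGGACAACATC	3	7	813	+	Pachon,Tinaja	yes
plg	insertion	290	290	T	4	20	2451	+	Pachon,Tinaja	yes
plg	deletion	294	294	C	4	20	2451	+	Pachon,Tinaja	yes
rnf126	deletion	1046	1050	AGTTC	11	11	1063	+	Pachon,Tinaja	yes
wdr1	insertion	626	631	TGAGAT	6	18	1674	-	Tinaja	no
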