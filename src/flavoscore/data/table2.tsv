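variant	structure_residue	yeast_mutation	effect_in_yeast	domain	d_fmn	d_fes	conservation	printed_score	printed_class
S56P	S36	-	-	N-terminus	23.7	38.3	None	0	none
R88G	R68	R87G	Complex I absent	N-terminus	4.5	21.0	All	16	strongly impaired
K111E	K91	-	-	Rossmann fold	16.7	25.1	Metazoans	6	mild
A117T	A97	A119T	Complex I absent	Rossmann fold	7.0	19.8	Metazoans	12	impaired
R147W	R127	R149W	Normal	Rossmann fold	16.7	31.9	Chordates	4	mild
R199P	R179	R201P	Normal	Rossmann fold	14.5	21.1	Eukaryotes	10	mild
Y204C	Y184	Y206C	Complex I absent	Rossmann fold	5.9	8.9	All	20	strongly impaired
C206G	C186	C208G	No flavin	Rossmann fold	7.0	9.2	All	20	strongly impaired
A211V	A191	-	-	Rossmann fold	8.5	8.5	Metazoans	16	strongly impaired
E214K	E194	E216K	Impaired	Rossmann fold	12.5	12.0	Eukaryotes	14	impaired
E246K	E226	E248K	Complex I absent	Rossmann fold	7.2	23.8	All	14	impaired
P252R	P232	P254R	Complex I absent	Rossmann fold	13.3	31.5	Eukaryotes	10	mild
R257Q	R237	R259Q	Complex I absent	Rossmann fold	19.9	38.5	Eukaryotes	8	mild
A341V	A321	A343V	Normal	Ubiquitin-like	17.5	26.7	Chordates	4	none
E377K	E357	E379K	No flavin	FeS domain	8.3	6.0	All	20	strongly impaired
R386C	R366	R388C	Impaired	FeS domain	14.0	6.3	All	18	strongly impaired
R386H	R366	R388H	Impaired	FeS domain	14.0	6.3	All	18	strongly impaired
T423M	T403	T425M	Complex I absent	FeS domain	10.0	5.1	Eukaryotes	16	strongly impaired
A432P	A412	A434P	Impaired	FeS domain	10.1	8.9	Eukaryotes	16	strongly impaired
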