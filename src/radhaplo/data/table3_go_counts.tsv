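go_term	go_annotation	freshwater_count	saltwater_count
F:0005247	Voltage-gated chloride channel activity	0	34
F:0005254	Chloride channel activity	0	29
C:0034707	Chloride channel complex	0	25
F:0005381	Iron ion transmembrane transporter activity	0	22
F:0015093	Ferrous iron transmembrane transporter activity	0	22
P:0034755	Iron ion transmembrane transport	0	22
P:0072511	Divalent inorganic cation transport	0	22
C:0033573	High-affinity iron permease complex	0	20
P:0006268	DNA unwinding involved in DNA replication	0	20
F:0008886	Glyceraldehyde-3-phosphate dehydrogenase (NADP+) (non-phosphorylating) activity	0	19
P:0031460	Glycine betaine transport	0	17
P:0009115	Xanthine catabolic process	0	17
C:0033177	Proton-transporting two-sector ATPase complex, proton-transporting domain	0	17
F:0004855	Xanthine oxidase activity	0	17
C:0033179	Proton-transporting V-type ATPase, V0 domain	0	17
P:0071705	Nitrogen compound transport	0	17
P:0009863	Salicylic acid mediated signaling pathway	0	17
F:0004854	Xanthine dehydrogenase activity	0	17
F:0043047	Single-stranded telomeric DNA binding	0	16
P:0015847	Putrescine transport	0	16
P:0075522	IRES-dependent viral translational initiation	24	0
P:0032790	Ribosome disassembly	24	0
P:0003091	Renal water homeostasis	14	0
P:0003096	Renal sodium ion transport	12	0
P:0055074	Calcium ion homeostasis	12	0
P:0035812	Renal sodium excretion	12	0
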