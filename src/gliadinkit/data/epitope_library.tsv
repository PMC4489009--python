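name	sequence	gliadin_class	notes
DQ2.5-glia-α1a	PFPQPQLPY	α	CD T-cell epitope; resides in the N-terminal repetitive domain
DQ2.5-glia-α1b	PYPQPQLPY	α	CD T-cell epitope
DQ2.5-glia-α2	PQPQLPYPQ	α	CD T-cell epitope; typically absent from A-genome α-gliadins
DQ2.5-glia-α3	FRPQQPYPQ	α	CD T-cell epitope; most widespread α epitope in this family
DQ8-glia-α1	QGSFQPSQQ	α	CD T-cell epitope; also nominated DQ8.5-glia-α1; resides in UII
19-residue-peptide	LGQQQPFPPQQPYPQPQPF	α	immunoreactive 19-mer of the N-terminal repetitive domain
12-residue-peptide	LGQGSFRPSQQN	α	immunoreactive 12-mer of unique domain II (UII)
DQ2.5-glia-γ1	PQQSFPQQQ	γ	CD T-cell epitope
DQ2.5-glia-γ2	IQPQQPAQL	γ	CD T-cell epitope
DQ2.5-glia-γ3	QQPQQPYPQ	γ	CD T-cell epitope
DQ2.5-glia-γ4a	SQPQQQFPQ	γ	CD T-cell epitope
DQ2.5-glia-γ4b	PQPQQQFPQ	γ	CD T-cell epitope
DQ2.5-glia-γ4c	QQPQQPFPQ	γ	CD T-cell epitope
DQ2.5-glia-γ4d	PQPQQPFCQ	γ	CD T-cell epitope
DQ2.5-glia-γ5	QQPFPQQPQ	γ	CD T-cell epitope
DQ8-glia-γ1a	QQPQQPFPQ	γ	same sequence as DQ2.5-glia-γ4c; deamidated at a different position by TG2
DQ8-glia-γ1b	QQPQQPYPQ	γ	same sequence as DQ2.5-glia-γ3; deamidated at a different position by TG2
DQ8.5-glia-γ1	PQQSFPQQQ	γ	same sequence as DQ2.5-glia-γ1; deamidated at a different position by TG2
DQ2.5-glia-ω1	PFPQPQQPF	ω	CD T-cell epitope
DQ2.5-glia-ω2	PQPQQPFPW	ω	CD T-cell epitope
hepta-QQIPQQQ	QQIPQQQ	ω	immunoreactive heptapeptide
hepta-QQLPQQQ	QQLPQQQ	ω	immunoreactive heptapeptide
hepta-QQFPQQQ	QQFPQQQ	ω	immunoreactive heptapeptide
hepta-QQSPQQQ	QQSPQQQ	ω	immunoreactive heptapeptide
hepta-QQSPEQQ	QQSPEQQ	ω	immunoreactive heptapeptide
hepta-QQYPQQQ	QQYPQQQ	ω	immunoreactive heptapeptide
hepta-QSPEQQQ	QSPEQQQ	ω	immunoreactive heptapeptide
hepta-YQQYPQQ	YQQYPQQ	ω	immunoreactive heptapeptide
hepta-QQFHQQQ	QQFHQQQ	ω	immunoreactive heptapeptide
tetra-QQQP	QQQP	ω	toxic tetrapeptide of the ω repetitive region
tetra-PYPP	PYPP	ω	toxic tetrapeptide
hexa-QQPPQQ	QQPPQQ	ω	immunoreactive hexapeptide (introductory enumeration)
hexa-QQFPQQ	QQFPQQ	ω	immunoreactive hexapeptide as reported in the Gli-ω-2 repetitive region; retained alongside QQPPQQ, the two published spellings disagree
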