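gene	genbank_id	cdna	genome_id	fragment_length	predicted_aa_length	n_cysteines
Gli-α-1	KP280186	N	NA	852	pseudo	6
Gli-α-2	KP280187	Y	NA	843	281	6
Gli-α-3	KP280197	Y	NA	834	278	6
Gli-α-4	KP280198	N	NA	906	302	6
Gli-α-5	KP280199	Y	TRIUR3_32056	858	286	6
Gli-α-6	KP280200	N	NA	876	292	6
Gli-α-7	KP280201	Y	NA	885	295	6
Gli-α-8	KP280202	Y	NA	855	285	6
Gli-α-9	KP280203	N	NA	864	288	6
Gli-α-10	KP280176	N	TRIUR3_24642	909	303	6
Gli-α-11	KP280177	Y	NA	903	301	6
Gli-α-12	KP280178	Y	NA	882	294	6
Gli-α-13	KP280179	Y	TRIUR3_24643	864	287	6
Gli-α-14	KP280180	N	TRIUR3_35338	833	pseudo	6
Gli-α-15	KP280181	N	NA	786	pseudo	5
Gli-α-16	KP280182	N	NA	786	pseudo	5
Gli-α-17	KP280183	N	NA	850	pseudo	7
Gli-α-18	KP280184	N	NA	847	pseudo	7
Gli-α-19	KP280185	N	NA	841	pseudo	7
Gli-α-20	KP280188	N	TRIUR3_28870	848	pseudo	6
Gli-α-21	KP280189	N	TRIUR3_34337	858	pseudo	6
Gli-α-22	KP280190	N	TRIUR3_28127	885	pseudo	6
Gli-α-23	KP280191	N	TRIUR3_29675	905	pseudo	6
Gli-γ-1	KP280192	Y	NA	858	286	8
Gli-γ-2	KP280193	Y	NA	837	279	8
Gli-γ-3	KP280194	Y	TRIUR3_27774	1026	342	8
Gli-ω-1	KP280195	Y	NA	975	325	0
Gli-ω-2	KP280196	N	NA	1248	pseudo	0
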