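spot	percent_volume	gene	mw_kd	pi
1	1.98	Gli-α-2	32.11	8.27
1	1.98	Gli-α-3	31.63	8.27
2	5.09	Gli-α-4	34.75	8.49
3	4.71	Gli-α-5	32.79	7.71
3	4.71	Gli-α-6	33.53	7.71
3	4.71	Gli-α-7	33.92	7.71
3	4.71	Gli-α-12	33.80	7.72
4	12.00	Gli-α-8	32.62	7.31
5	2.21	Gli-α-9	33.06	6.69
6	18.79	Gli-α-10	34.94	8.02
6	18.79	Gli-α-11	34.70	8.02
7	1.84	Gli-α-13	33.05	6.90
8	26.80	Gli-γ-1	32.67	8.33
9	10.86	Gli-γ-1	32.67	8.33
10	11.61	Gli-γ-1	32.67	8.33
11	3.54	Gli-γ-2	31.81	8.33
12	0.58	Gli-γ-3	39.12	7.60
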