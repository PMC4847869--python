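population	latitude	n_lines	n_alleles	del_alleles	frequency	sub_saharan
Sweden	63.8	12	24	24	1.00	0
Denmark	55.7	12	24	23	0.96	0
Netherlands	52.2	12	24	20	0.83	0
Germany	48.1	11	22	20	0.91	0
France	45.8	12	24	22	0.92	0
Cyprus	35.1	10	20	13	0.65	0
Egypt	30.1	14	28	17	0.60	0
Cameroon	6.3	6	12	0	0.00	1
Malaysia	3.1	12	24	11	0.45	0
Rwanda	-2.5	12	24	2	0.08	1
Zambia	-16.5	10	20	1	0.05	1
Zimbabwe	-17.3	11	22	0	0.00	1
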