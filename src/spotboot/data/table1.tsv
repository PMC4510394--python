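spot_id	mean_control	se_control	bias_control	mean_dfd	se_dfd	bias_dfd
MYL3	2.16	0.46	0.6	0.00	N/A	N/A
MYL6B	13.6	8.41	17.2	2.40	0.71	10.6
MYL2	18.7	3.24	6.2	7.81	1.83	9.4
TNNC2	2.27	0.94	8.0	0.00	N/A	N/A
ST6GAL1	0.28	0.28	49.2	5.60	3.31	51.0
ATP5B	0.62	0.19	11.2	2.35	0.49	7.6
TPI1	3.03	0.12	6.0	6.83	2.61	10.2
CFL2	0.00	N/A	N/A	4.72	1.34	11.4
MYLPF	0.00	N/A	N/A	18.1	6.15	1.0
MYLPF-1	0.00	N/A	N/A	38.1	14.5	4.6
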