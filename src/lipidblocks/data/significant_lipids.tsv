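# Significantly altered plasma lipids (FDR < 0.05) in the fish-oil (FO) arm
# versus the high-oleic sunflower-oil (HOSO) arm after three weeks of
# supplementation, as printed in the source study's two results tables.
# q_value is kept as printed ("<0.001" marks a censored entry); fold changes
# are geometric fold changes from baseline within each arm.
table	lipid_name	q_value	fold_change_hoso	fold_change_fo
2	LysoPC(20:5)	<0.001	0.80	4.35
2	LysoPC(22:5)	0.025	0.91	1.67
2	LysoPC(22:6)	0.003	0.94	1.89
2	PA(38:5e)	0.006	1.05	0.75
2	PE(38:4)	0.026	1.11	0.88
2	PE(38:4)+PC(35:4)	0.029	1.27	0.90
2	PE(38:5)	<0.001	0.92	3.29
2	PE(38:5e)	0.042	1.09	0.75
2	PE(38:7e)	<0.001	1.17	2.58
2	PE(38:7e)	0.013	1.11	1.40
2	PE(40:4)	0.027	1.10	0.78
2	PE(40:6)	0.013	1.10	1.75
2	PE(40:7e)	0.010	1.08	1.51
2	PG(36:2)	0.015	0.96	0.68
2	PG(36:5e)	0.028	1.02	0.80
2	PG(38:4)	0.013	1.24	0.89
2	PG(40:6)	0.003	1.11	1.91
2	PI(40:7)	0.024	1.25	0.96
2	PS(36:1)	0.001	1.14	1.84
2	PS(38:0)	0.031	1.18	1.67
2	PS(38:1)	0.010	1.11	1.58
2	PS(38:1)	0.019	1.26	1.83
2	PS(41:5)	0.031	1.17	0.96
2	PS(42:1)	0.003	1.09	1.86
2	PS(42:6)	0.001	0.96	1.54
2	PS(42:7)	0.001	0.92	1.39
2	PS(42:8)	0.001	1.36	2.51
2	PS(44:1)	0.001	1.08	1.86
2	SM(d18:0/20:0)	0.029	1.08	0.81
2	SM(d18:0/22:6)	0.015	1.01	1.44
2	SM(d18:0/24:0)	<0.001	0.93	2.62
2	SM(d18:1/26:2)	0.015	1.10	1.43
3	PC(30:3)	0.015	0.85	0.6
3	PC(32:5)	0.024	1.03	0.77
3	PC(36:3)	0.031	0.97	0.73
3	PC(36:5)	<0.001	0.80	4.00
3	PC(37:4)/PE(40:4)	0.021	1.07	0.83
3	PC(38:1)	0.025	1.05	1.60
3	PC(38:1e)	0.026	0.91	1.39
3	PC(38:4)	0.007	2.35	9.08
3	PC(38:5)	<0.001	1.12	3.97
3	PC(38:5e)	0.006	1.2	0.96
3	PC(38:6)	0.006	1.15	1.52
3	PC(38:6)	0.037	0.89	0.69
3	PC(38:7)	0.001	1.09	2.27
3	PC(38:7)	0.001	1.09	2.25
3	PC(40:2)	<0.001	0.99	3.54
3	PC(40:3)	0.001	0.93	1.74
3	PC(40:4)	0.029	1.09	0.79
3	PC(40:4e)	0.015	1.01	0.78
3	PC(40:5)	<0.001	0.89	1.57
3	PC(40:6)	<0.001	1.04	1.71
3	TG(50:4)	<0.001	1.04	3.57
3	TG(52:0)	0.001	1.03	2.52
3	TG(52:2)	0.029	1.09	0.79
3	TG(52:6)	0.004	0.96	2.86
3	TG(52:7)	<0.001	0.80	4.55
3	TG(54:2)	0.001	1.27	0.59
3	TG(54:3)	0.029	1.26	0.83
3	TG(54:4)	<0.001	0.96	2.34
3	TG(54:4)	0.003	0.97	1.73
3	TG(54:5)	0.022	1.51	0.82
3	TG(54:8)	<0.001	0.98	5.02
3	TG(56:2)	0.026	1.02	1.93
3	TG(56:4)	0.038	4.50	1.47
3	TG(56:7)	<0.001	1.09	3.02
3	TG(56:8)	<0.001	1.27	2.71
3	TG(56:9)	<0.001	1.01	4.76
3	TG(58:10)	<0.001	1.17	4.14
3	TG(58:6)	0.003	1.17	2.10
3	TG(58:6)	0.023	0.99	1.70
3	TG(58:8)	<0.001	1.36	4.07
3	TG(58:9)	0.001	1.48	4.05
3	TG(59:2)	<0.001	1.08	2.73
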