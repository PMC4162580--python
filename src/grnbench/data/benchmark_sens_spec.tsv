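approach	dataset	sensitivity	specificity
BIVARIATE_Z_FDR_AND	Holstege1	0.63	0.37
BIVARIATE_Z_FDR_AND	Holstege2	0.79	0.22
BIVARIATE_Z_FDR_AND	Gresham	0.58	0.44
BIVARIATE_Z_FDR_AND	Gasch	0.49	0.53
BIVARIATE_Z_FDR_AND	Smith	0.76	0.28
BIVARIATE_Z_FDR_AND	Yeung	0.75	0.19
BIVARIATE_Z_FDR_AND	M3D	0.74	0.26
BIVARIATE_Z_FDR_AND	GPL90	0.78	0.25
BIVARIATE_Z_FDR_AND	Hughes1	0.43	0.65
BIVARIATE_Z_FDR_AND	Hughes2	0.35	0.73
BIVARIATE_Z_FDR_AND	Hu	0.33	0.68
BIVARIATE_Z_FDR_AND	Holstege3	0.73	0.25
BIVARIATE_Z_FDR_AND	Holstege4	0.71	0.33
BIVARIATE_Z_FDR_OR	Holstege1	0.65	0.35
BIVARIATE_Z_FDR_OR	Holstege2	0.81	0.2
BIVARIATE_Z_FDR_OR	Gresham	0.62	0.41
BIVARIATE_Z_FDR_OR	Gasch	0.53	0.49
BIVARIATE_Z_FDR_OR	Smith	0.8	0.25
BIVARIATE_Z_FDR_OR	Yeung	0.77	0.18
BIVARIATE_Z_FDR_OR	M3D	0.76	0.25
BIVARIATE_Z_FDR_OR	GPL90	0.79	0.24
BIVARIATE_Z_FDR_OR	Hughes1	0.45	0.61
BIVARIATE_Z_FDR_OR	Hughes2	0.38	0.69
BIVARIATE_Z_FDR_OR	Hu	0.36	0.64
BIVARIATE_Z_FDR_OR	Holstege3	0.74	0.24
BIVARIATE_Z_FDR_OR	Holstege4	0.72	0.31
BIVARIATE_Z_ALPHA	Holstege1	0.68	0.32
BIVARIATE_Z_ALPHA	Holstege2	0.82	0.2
BIVARIATE_Z_ALPHA	Gresham	0.65	0.38
BIVARIATE_Z_ALPHA	Gasch	0.57	0.45
BIVARIATE_Z_ALPHA	Smith	0.81	0.23
BIVARIATE_Z_ALPHA	Yeung	0.78	0.17
BIVARIATE_Z_ALPHA	M3D	0.77	0.24
BIVARIATE_Z_ALPHA	GPL90	0.8	0.23
BIVARIATE_Z_ALPHA	Hughes1	0.52	0.54
BIVARIATE_Z_ALPHA	Hughes2	0.47	0.61
BIVARIATE_Z_ALPHA	Hu	0.43	0.57
BIVARIATE_Z_ALPHA	Holstege3	0.77	0.22
BIVARIATE_Z_ALPHA	Holstege4	0.75	0.29
GLL_Z_1_AND	Holstege1	0.06	0.94
GLL_Z_1_AND	Holstege2	0.06	0.95
GLL_Z_1_AND	Gresham	0.03	0.97
GLL_Z_1_AND	Gasch	0.07	0.96
GLL_Z_1_AND	Smith	0.1	0.95
GLL_Z_1_AND	Yeung	0.11	0.93
GLL_Z_1_AND	M3D	0.15	0.91
GLL_Z_1_AND	GPL90	0.2	0.85
GLL_Z_1_AND	Hughes1	0.11	0.92
GLL_Z_1_AND	Hughes2	0.11	0.93
GLL_Z_1_AND	Hu	0.07	0.94
GLL_Z_1_AND	Holstege3	0.12	0.88
GLL_Z_1_AND	Holstege4	0.14	0.91
GLL_Z_1_OR	Holstege1	0.07	0.94
GLL_Z_1_OR	Holstege2	0.07	0.94
GLL_Z_1_OR	Gresham	0.04	0.97
GLL_Z_1_OR	Gasch	0.07	0.96
GLL_Z_1_OR	Smith	0.12	0.94
GLL_Z_1_OR	Yeung	0.11	0.92
GLL_Z_1_OR	M3D	0.16	0.9
GLL_Z_1_OR	GPL90	0.21	0.84
GLL_Z_1_OR	Hughes1	0.12	0.91
GLL_Z_1_OR	Hughes2	0.12	0.93
GLL_Z_1_OR	Hu	0.07	0.93
GLL_Z_1_OR	Holstege3	0.13	0.88
GLL_Z_1_OR	Holstege4	0.15	0.9
GLL_Z_2_AND	Holstege1	0.01	0.99
GLL_Z_2_AND	Holstege2	0.01	0.99
GLL_Z_2_AND	Gresham	0.01	1.0
GLL_Z_2_AND	Gasch	0.02	0.99
GLL_Z_2_AND	Smith	0.03	0.99
GLL_Z_2_AND	Yeung	0.03	0.99
GLL_Z_2_AND	M3D	0.03	0.98
GLL_Z_2_AND	GPL90	0.06	0.96
GLL_Z_2_AND	Hughes1	0.03	0.98
GLL_Z_2_AND	Hughes2	0.04	0.98
GLL_Z_2_AND	Hu	0.02	0.98
GLL_Z_2_AND	Holstege3	0.04	0.98
GLL_Z_2_AND	Holstege4	0.03	0.98
GLL_Z_2_OR	Holstege1	0.02	0.98
GLL_Z_2_OR	Holstege2	0.02	0.98
GLL_Z_2_OR	Gresham	0.02	0.99
GLL_Z_2_OR	Gasch	0.03	0.99
GLL_Z_2_OR	Smith	0.04	0.98
GLL_Z_2_OR	Yeung	0.05	0.98
GLL_Z_2_OR	M3D	0.05	0.97
GLL_Z_2_OR	GPL90	0.08	0.95
GLL_Z_2_OR	Hughes1	0.04	0.97
GLL_Z_2_OR	Hughes2	0.05	0.97
GLL_Z_2_OR	Hu	0.03	0.98
GLL_Z_2_OR	Holstege3	0.05	0.96
GLL_Z_2_OR	Holstege4	0.05	0.97
GLL_Z_3_AND	Holstege1	0.01	1.0
GLL_Z_3_AND	Holstege2	0.01	1.0
GLL_Z_3_AND	Gresham	0.0	1.0
GLL_Z_3_AND	Gasch	0.01	1.0
GLL_Z_3_AND	Smith	0.03	0.99
GLL_Z_3_AND	Yeung	0.02	0.99
GLL_Z_3_AND	M3D	0.01	0.99
GLL_Z_3_AND	GPL90	0.03	0.98
GLL_Z_3_AND	Hughes1	0.02	0.99
GLL_Z_3_AND	Hughes2	0.02	0.99
GLL_Z_3_AND	Hu	0.01	0.99
GLL_Z_3_AND	Holstege3	0.02	0.99
GLL_Z_3_AND	Holstege4	0.02	0.99
GLL_Z_3_OR	Holstege1	0.02	0.99
GLL_Z_3_OR	Holstege2	0.01	0.99
GLL_Z_3_OR	Gresham	0.01	0.99
GLL_Z_3_OR	Gasch	0.02	0.99
GLL_Z_3_OR	Smith	0.04	0.99
GLL_Z_3_OR	Yeung	0.04	0.98
GLL_Z_3_OR	M3D	0.04	0.98
GLL_Z_3_OR	GPL90	0.05	0.97
GLL_Z_3_OR	Hughes1	0.03	0.98
GLL_Z_3_OR	Hughes2	0.04	0.98
GLL_Z_3_OR	Hu	0.02	0.98
GLL_Z_3_OR	Holstege3	0.04	0.98
GLL_Z_3_OR	Holstege4	0.04	0.98
BIVARIATE_G_FDR_AND	Holstege1	0.39	0.59
BIVARIATE_G_FDR_AND	Holstege2	0.62	0.37
BIVARIATE_G_FDR_AND	Gresham	0.49	0.5
BIVARIATE_G_FDR_AND	Gasch	0.43	0.59
BIVARIATE_G_FDR_AND	Smith	0.71	0.34
BIVARIATE_G_FDR_AND	Yeung	0.8	0.14
BIVARIATE_G_FDR_AND	M3D	0.9	0.11
BIVARIATE_G_FDR_AND	GPL90	0.89	0.16
BIVARIATE_G_FDR_AND	Hughes1	0.24	0.83
BIVARIATE_G_FDR_AND	Hughes2	0.32	0.76
BIVARIATE_G_FDR_AND	Hu	0.21	0.8
BIVARIATE_G_FDR_AND	Holstege3	0.69	0.3
BIVARIATE_G_FDR_AND	Holstege4	0.66	0.38
BIVARIATE_G_FDR_OR	Holstege1	0.44	0.54
BIVARIATE_G_FDR_OR	Holstege2	0.66	0.33
BIVARIATE_G_FDR_OR	Gresham	0.56	0.44
BIVARIATE_G_FDR_OR	Gasch	0.5	0.52
BIVARIATE_G_FDR_OR	Smith	0.76	0.28
BIVARIATE_G_FDR_OR	Yeung	0.82	0.12
BIVARIATE_G_FDR_OR	M3D	0.91	0.11
BIVARIATE_G_FDR_OR	GPL90	0.9	0.15
BIVARIATE_G_FDR_OR	Hughes1	0.3	0.78
BIVARIATE_G_FDR_OR	Hughes2	0.39	0.69
BIVARIATE_G_FDR_OR	Hu	0.26	0.74
BIVARIATE_G_FDR_OR	Holstege3	0.72	0.27
BIVARIATE_G_FDR_OR	Holstege4	0.71	0.33
BIVARIATE_G_ALPHA	Holstege1	0.5	0.49
BIVARIATE_G_ALPHA	Holstege2	0.69	0.31
BIVARIATE_G_ALPHA	Gresham	0.6	0.38
BIVARIATE_G_ALPHA	Gasch	0.55	0.47
BIVARIATE_G_ALPHA	Smith	0.79	0.25
BIVARIATE_G_ALPHA	Yeung	0.83	0.12
BIVARIATE_G_ALPHA	M3D	0.91	0.1
BIVARIATE_G_ALPHA	GPL90	0.9	0.14
BIVARIATE_G_ALPHA	Hughes1	0.43	0.65
BIVARIATE_G_ALPHA	Hughes2	0.52	0.58
BIVARIATE_G_ALPHA	Hu	0.36	0.65
BIVARIATE_G_ALPHA	Holstege3	0.76	0.23
BIVARIATE_G_ALPHA	Holstege4	0.76	0.29
GLL_G_1_AND	Holstege1	0.04	0.96
GLL_G_1_AND	Holstege2	0.14	0.86
GLL_G_1_AND	Gresham	0.59	0.39
GLL_G_1_AND	Gasch	0.04	0.98
GLL_G_1_AND	Smith	0.19	0.87
GLL_G_1_AND	Yeung	0.25	0.78
GLL_G_1_AND	M3D	0.37	0.68
GLL_G_1_AND	GPL90	0.47	0.59
GLL_G_1_AND	Hughes1	0.02	0.99
GLL_G_1_AND	Hughes2	0.02	0.99
GLL_G_1_AND	Hu	0.04	0.98
GLL_G_1_AND	Holstege3	0.14	0.85
GLL_G_1_AND	Holstege4	0.14	0.9
GLL_G_1_OR	Holstege1	0.04	0.95
GLL_G_1_OR	Holstege2	0.15	0.85
GLL_G_1_OR	Gresham	0.6	0.38
GLL_G_1_OR	Gasch	0.06	0.96
GLL_G_1_OR	Smith	0.22	0.85
GLL_G_1_OR	Yeung	0.26	0.77
GLL_G_1_OR	M3D	0.39	0.66
GLL_G_1_OR	GPL90	0.48	0.59
GLL_G_1_OR	Hughes1	0.04	0.97
GLL_G_1_OR	Hughes2	0.04	0.97
GLL_G_1_OR	Hu	0.05	0.97
GLL_G_1_OR	Holstege3	0.16	0.83
GLL_G_1_OR	Holstege4	0.17	0.88
GLL_G_2_AND	Holstege1	0.04	0.96
GLL_G_2_AND	Holstege2	0.14	0.86
GLL_G_2_AND	Gresham	0.52	0.47
GLL_G_2_AND	Gasch	0.04	0.98
GLL_G_2_AND	Smith	0.19	0.87
GLL_G_2_AND	Yeung	0.04	0.98
GLL_G_2_AND	M3D	0.06	0.97
GLL_G_2_AND	GPL90	0.15	0.9
GLL_G_2_AND	Hughes1	0.02	0.99
GLL_G_2_AND	Hughes2	0.02	0.99
GLL_G_2_AND	Hu	0.04	0.98
GLL_G_2_AND	Holstege3	0.02	0.98
GLL_G_2_AND	Holstege4	0.14	0.9
GLL_G_2_OR	Holstege1	0.04	0.95
GLL_G_2_OR	Holstege2	0.15	0.85
GLL_G_2_OR	Gresham	0.6	0.39
GLL_G_2_OR	Gasch	0.06	0.96
GLL_G_2_OR	Smith	0.22	0.85
GLL_G_2_OR	Yeung	0.06	0.97
GLL_G_2_OR	M3D	0.09	0.93
GLL_G_2_OR	GPL90	0.17	0.87
GLL_G_2_OR	Hughes1	0.04	0.97
GLL_G_2_OR	Hughes2	0.04	0.97
GLL_G_2_OR	Hu	0.05	0.97
GLL_G_2_OR	Holstege3	0.04	0.96
GLL_G_2_OR	Holstege4	0.17	0.88
GLL_G_3_AND	Holstege1	0.04	0.96
GLL_G_3_AND	Holstege2	0.09	0.91
GLL_G_3_AND	Gresham	0.09	0.89
GLL_G_3_AND	Gasch	0.03	0.98
GLL_G_3_AND	Smith	0.16	0.91
GLL_G_3_AND	Yeung	0.04	0.98
GLL_G_3_AND	M3D	0.06	0.97
GLL_G_3_AND	GPL90	0.06	0.97
GLL_G_3_AND	Hughes1	0.02	0.99
GLL_G_3_AND	Hughes2	0.02	0.99
GLL_G_3_AND	Hu	0.04	0.98
GLL_G_3_AND	Holstege3	0.02	0.98
GLL_G_3_AND	Holstege4	0.14	0.9
GLL_G_3_OR	Holstege1	0.04	0.95
GLL_G_3_OR	Holstege2	0.14	0.86
GLL_G_3_OR	Gresham	0.28	0.73
GLL_G_3_OR	Gasch	0.06	0.96
GLL_G_3_OR	Smith	0.21	0.86
GLL_G_3_OR	Yeung	0.06	0.97
GLL_G_3_OR	M3D	0.09	0.93
GLL_G_3_OR	GPL90	0.09	0.95
GLL_G_3_OR	Hughes1	0.04	0.97
GLL_G_3_OR	Hughes2	0.04	0.97
GLL_G_3_OR	Hu	0.05	0.97
GLL_G_3_OR	Holstege3	0.04	0.96
GLL_G_3_OR	Holstege4	0.17	0.88
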