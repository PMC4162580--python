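approach	dataset	ppv	npv
BIVARIATE_Z_FDR_AND	Holstege1	0.02	0.98
BIVARIATE_Z_FDR_AND	Holstege2	0.02	0.98
BIVARIATE_Z_FDR_AND	Gresham	0.02	0.98
BIVARIATE_Z_FDR_AND	Gasch	0.02	0.98
BIVARIATE_Z_FDR_AND	Smith	0.02	0.99
BIVARIATE_Z_FDR_AND	Yeung	0.02	0.98
BIVARIATE_Z_FDR_AND	M3D	0.02	0.98
BIVARIATE_Z_FDR_AND	GPL90	0.02	0.98
BIVARIATE_Z_FDR_AND	Hughes1	0.02	0.98
BIVARIATE_Z_FDR_AND	Hughes2	0.02	0.98
BIVARIATE_Z_FDR_AND	Hu	0.02	0.98
BIVARIATE_Z_FDR_AND	Holstege3	0.02	0.98
BIVARIATE_Z_FDR_AND	Holstege4	0.02	0.98
BIVARIATE_Z_FDR_OR	Holstege1	0.02	0.98
BIVARIATE_Z_FDR_OR	Holstege2	0.02	0.98
BIVARIATE_Z_FDR_OR	Gresham	0.02	0.98
BIVARIATE_Z_FDR_OR	Gasch	0.02	0.98
BIVARIATE_Z_FDR_OR	Smith	0.02	0.99
BIVARIATE_Z_FDR_OR	Yeung	0.02	0.98
BIVARIATE_Z_FDR_OR	M3D	0.02	0.98
BIVARIATE_Z_FDR_OR	GPL90	0.02	0.99
BIVARIATE_Z_FDR_OR	Hughes1	0.02	0.98
BIVARIATE_Z_FDR_OR	Hughes2	0.02	0.98
BIVARIATE_Z_FDR_OR	Hu	0.02	0.98
BIVARIATE_Z_FDR_OR	Holstege3	0.02	0.98
BIVARIATE_Z_FDR_OR	Holstege4	0.02	0.98
BIVARIATE_Z_ALPHA	Holstege1	0.02	0.98
BIVARIATE_Z_ALPHA	Holstege2	0.02	0.98
BIVARIATE_Z_ALPHA	Gresham	0.02	0.98
BIVARIATE_Z_ALPHA	Gasch	0.02	0.98
BIVARIATE_Z_ALPHA	Smith	0.02	0.99
BIVARIATE_Z_ALPHA	Yeung	0.02	0.98
BIVARIATE_Z_ALPHA	M3D	0.02	0.98
BIVARIATE_Z_ALPHA	GPL90	0.02	0.98
BIVARIATE_Z_ALPHA	Hughes1	0.02	0.98
BIVARIATE_Z_ALPHA	Hughes2	0.02	0.99
BIVARIATE_Z_ALPHA	Hu	0.02	0.98
BIVARIATE_Z_ALPHA	Holstege3	0.02	0.98
BIVARIATE_Z_ALPHA	Holstege4	0.02	0.98
GLL_Z_1_AND	Holstege1	0.02	0.98
GLL_Z_1_AND	Holstege2	0.02	0.98
GLL_Z_1_AND	Gresham	0.02	0.98
GLL_Z_1_AND	Gasch	0.03	0.98
GLL_Z_1_AND	Smith	0.03	0.98
GLL_Z_1_AND	Yeung	0.02	0.98
GLL_Z_1_AND	M3D	0.03	0.98
GLL_Z_1_AND	GPL90	0.02	0.98
GLL_Z_1_AND	Hughes1	0.02	0.98
GLL_Z_1_AND	Hughes2	0.03	0.98
GLL_Z_1_AND	Hu	0.02	0.98
GLL_Z_1_AND	Holstege3	0.02	0.98
GLL_Z_1_AND	Holstege4	0.03	0.98
GLL_Z_1_OR	Holstege1	0.02	0.98
GLL_Z_1_OR	Holstege2	0.02	0.98
GLL_Z_1_OR	Gresham	0.02	0.98
GLL_Z_1_OR	Gasch	0.03	0.98
GLL_Z_1_OR	Smith	0.03	0.98
GLL_Z_1_OR	Yeung	0.02	0.98
GLL_Z_1_OR	M3D	0.03	0.98
GLL_Z_1_OR	GPL90	0.02	0.98
GLL_Z_1_OR	Hughes1	0.02	0.98
GLL_Z_1_OR	Hughes2	0.03	0.98
GLL_Z_1_OR	Hu	0.02	0.98
GLL_Z_1_OR	Holstege3	0.02	0.98
GLL_Z_1_OR	Holstege4	0.03	0.98
GLL_Z_2_AND	Holstege1	0.02	0.98
GLL_Z_2_AND	Holstege2	0.02	0.98
GLL_Z_2_AND	Gresham	0.03	0.98
GLL_Z_2_AND	Gasch	0.04	0.98
GLL_Z_2_AND	Smith	0.05	0.98
GLL_Z_2_AND	Yeung	0.04	0.98
GLL_Z_2_AND	M3D	0.03	0.98
GLL_Z_2_AND	GPL90	0.03	0.98
GLL_Z_2_AND	Hughes1	0.03	0.98
GLL_Z_2_AND	Hughes2	0.04	0.98
GLL_Z_2_AND	Hu	0.02	0.98
GLL_Z_2_AND	Holstege3	0.03	0.98
GLL_Z_2_AND	Holstege4	0.04	0.98
GLL_Z_2_OR	Holstege1	0.02	0.98
GLL_Z_2_OR	Holstege2	0.03	0.98
GLL_Z_2_OR	Gresham	0.02	0.98
GLL_Z_2_OR	Gasch	0.04	0.98
GLL_Z_2_OR	Smith	0.04	0.98
GLL_Z_2_OR	Yeung	0.03	0.98
GLL_Z_2_OR	M3D	0.03	0.98
GLL_Z_2_OR	GPL90	0.03	0.98
GLL_Z_2_OR	Hughes1	0.02	0.98
GLL_Z_2_OR	Hughes2	0.03	0.98
GLL_Z_2_OR	Hu	0.02	0.98
GLL_Z_2_OR	Holstege3	0.02	0.98
GLL_Z_2_OR	Holstege4	0.03	0.98
GLL_Z_3_AND	Holstege1	0.02	0.98
GLL_Z_3_AND	Holstege2	0.03	0.98
GLL_Z_3_AND	Gresham	0.01	0.98
GLL_Z_3_AND	Gasch	0.05	0.98
GLL_Z_3_AND	Smith	0.07	0.98
GLL_Z_3_AND	Yeung	0.05	0.98
GLL_Z_3_AND	M3D	0.03	0.98
GLL_Z_3_AND	GPL90	0.03	0.98
GLL_Z_3_AND	Hughes1	0.03	0.98
GLL_Z_3_AND	Hughes2	0.05	0.98
GLL_Z_3_AND	Hu	0.03	0.98
GLL_Z_3_AND	Holstege3	0.03	0.98
GLL_Z_3_AND	Holstege4	0.05	0.98
GLL_Z_3_OR	Holstege1	0.02	0.98
GLL_Z_3_OR	Holstege2	0.02	0.98
GLL_Z_3_OR	Gresham	0.02	0.98
GLL_Z_3_OR	Gasch	0.03	0.98
GLL_Z_3_OR	Smith	0.05	0.98
GLL_Z_3_OR	Yeung	0.04	0.98
GLL_Z_3_OR	M3D	0.04	0.98
GLL_Z_3_OR	GPL90	0.03	0.98
GLL_Z_3_OR	Hughes1	0.03	0.98
GLL_Z_3_OR	Hughes2	0.04	0.98
GLL_Z_3_OR	Hu	0.03	0.98
GLL_Z_3_OR	Holstege3	0.03	0.98
GLL_Z_3_OR	Holstege4	0.03	0.98
BIVARIATE_G_FDR_AND	Holstege1	0.02	0.98
BIVARIATE_G_FDR_AND	Holstege2	0.02	0.98
BIVARIATE_G_FDR_AND	Gresham	0.02	0.98
BIVARIATE_G_FDR_AND	Gasch	0.02	0.98
BIVARIATE_G_FDR_AND	Smith	0.02	0.99
BIVARIATE_G_FDR_AND	Yeung	0.02	0.97
BIVARIATE_G_FDR_AND	M3D	0.02	0.98
BIVARIATE_G_FDR_AND	GPL90	0.02	0.99
BIVARIATE_G_FDR_AND	Hughes1	0.02	0.98
BIVARIATE_G_FDR_AND	Hughes2	0.02	0.98
BIVARIATE_G_FDR_AND	Hu	0.02	0.98
BIVARIATE_G_FDR_AND	Holstege3	0.02	0.98
BIVARIATE_G_FDR_AND	Holstege4	0.02	0.98
BIVARIATE_G_FDR_OR	Holstege1	0.02	0.98
BIVARIATE_G_FDR_OR	Holstege2	0.02	0.98
BIVARIATE_G_FDR_OR	Gresham	0.02	0.98
BIVARIATE_G_FDR_OR	Gasch	0.02	0.98
BIVARIATE_G_FDR_OR	Smith	0.02	0.99
BIVARIATE_G_FDR_OR	Yeung	0.02	0.98
BIVARIATE_G_FDR_OR	M3D	0.02	0.98
BIVARIATE_G_FDR_OR	GPL90	0.02	0.99
BIVARIATE_G_FDR_OR	Hughes1	0.02	0.98
BIVARIATE_G_FDR_OR	Hughes2	0.02	0.98
BIVARIATE_G_FDR_OR	Hu	0.02	0.98
BIVARIATE_G_FDR_OR	Holstege3	0.02	0.98
BIVARIATE_G_FDR_OR	Holstege4	0.02	0.99
BIVARIATE_G_ALPHA	Holstege1	0.02	0.98
BIVARIATE_G_ALPHA	Holstege2	0.02	0.98
BIVARIATE_G_ALPHA	Gresham	0.02	0.98
BIVARIATE_G_ALPHA	Gasch	0.02	0.98
BIVARIATE_G_ALPHA	Smith	0.02	0.99
BIVARIATE_G_ALPHA	Yeung	0.02	0.98
BIVARIATE_G_ALPHA	M3D	0.02	0.98
BIVARIATE_G_ALPHA	GPL90	0.02	0.99
BIVARIATE_G_ALPHA	Hughes1	0.02	0.98
BIVARIATE_G_ALPHA	Hughes2	0.02	0.99
BIVARIATE_G_ALPHA	Hu	0.02	0.98
BIVARIATE_G_ALPHA	Holstege3	0.02	0.98
BIVARIATE_G_ALPHA	Holstege4	0.02	0.99
GLL_G_1_AND	Holstege1	0.01	0.98
GLL_G_1_AND	Holstege2	0.02	0.98
GLL_G_1_AND	Gresham	0.02	0.98
GLL_G_1_AND	Gasch	0.03	0.98
GLL_G_1_AND	Smith	0.03	0.98
GLL_G_1_AND	Yeung	0.02	0.98
GLL_G_1_AND	M3D	0.02	0.98
GLL_G_1_AND	GPL90	0.02	0.98
GLL_G_1_AND	Hughes1	0.03	0.98
GLL_G_1_AND	Hughes2	0.03	0.98
GLL_G_1_AND	Hu	0.03	0.98
GLL_G_1_AND	Holstege3	0.02	0.98
GLL_G_1_AND	Holstege4	0.02	0.98
GLL_G_1_OR	Holstege1	0.01	0.98
GLL_G_1_OR	Holstege2	0.02	0.98
GLL_G_1_OR	Gresham	0.02	0.98
GLL_G_1_OR	Gasch	0.03	0.98
GLL_G_1_OR	Smith	0.02	0.98
GLL_G_1_OR	Yeung	0.02	0.98
GLL_G_1_OR	M3D	0.02	0.98
GLL_G_1_OR	GPL90	0.02	0.98
GLL_G_1_OR	Hughes1	0.02	0.98
GLL_G_1_OR	Hughes2	0.03	0.98
GLL_G_1_OR	Hu	0.03	0.98
GLL_G_1_OR	Holstege3	0.02	0.98
GLL_G_1_OR	Holstege4	0.02	0.98
GLL_G_2_AND	Holstege1	0.01	0.98
GLL_G_2_AND	Holstege2	0.02	0.98
GLL_G_2_AND	Gresham	0.02	0.98
GLL_G_2_AND	Gasch	0.03	0.98
GLL_G_2_AND	Smith	0.03	0.98
GLL_G_2_AND	Yeung	0.04	0.98
GLL_G_2_AND	M3D	0.03	0.98
GLL_G_2_AND	GPL90	0.03	0.98
GLL_G_2_AND	Hughes1	0.03	0.98
GLL_G_2_AND	Hughes2	0.03	0.98
GLL_G_2_AND	Hu	0.03	0.98
GLL_G_2_AND	Holstege3	0.02	0.98
GLL_G_2_AND	Holstege4	0.02	0.98
GLL_G_2_OR	Holstege1	0.01	0.98
GLL_G_2_OR	Holstege2	0.02	0.98
GLL_G_2_OR	Gresham	0.02	0.98
GLL_G_2_OR	Gasch	0.03	0.98
GLL_G_2_OR	Smith	0.02	0.98
GLL_G_2_OR	Yeung	0.03	0.98
GLL_G_2_OR	M3D	0.02	0.98
GLL_G_2_OR	GPL90	0.02	0.98
GLL_G_2_OR	Hughes1	0.02	0.98
GLL_G_2_OR	Hughes2	0.03	0.98
GLL_G_2_OR	Hu	0.03	0.98
GLL_G_2_OR	Holstege3	0.02	0.98
GLL_G_2_OR	Holstege4	0.02	0.98
GLL_G_3_AND	Holstege1	0.01	0.98
GLL_G_3_AND	Holstege2	0.02	0.98
GLL_G_3_AND	Gresham	0.01	0.98
GLL_G_3_AND	Gasch	0.03	0.98
GLL_G_3_AND	Smith	0.03	0.98
GLL_G_3_AND	Yeung	0.04	0.98
GLL_G_3_AND	M3D	0.03	0.98
GLL_G_3_AND	GPL90	0.04	0.98
GLL_G_3_AND	Hughes1	0.03	0.98
GLL_G_3_AND	Hughes2	0.03	0.98
GLL_G_3_AND	Hu	0.03	0.98
GLL_G_3_AND	Holstege3	0.02	0.98
GLL_G_3_AND	Holstege4	0.02	0.98
GLL_G_3_OR	Holstege1	0.01	0.98
GLL_G_3_OR	Holstege2	0.02	0.98
GLL_G_3_OR	Gresham	0.02	0.98
GLL_G_3_OR	Gasch	0.03	0.98
GLL_G_3_OR	Smith	0.02	0.98
GLL_G_3_OR	Yeung	0.03	0.98
GLL_G_3_OR	M3D	0.02	0.98
GLL_G_3_OR	GPL90	0.03	0.98
GLL_G_3_OR	Hughes1	0.02	0.98
GLL_G_3_OR	Hughes2	0.03	0.98
GLL_G_3_OR	Hu	0.03	0.98
GLL_G_3_OR	Holstege3	0.02	0.98
GLL_G_3_OR	Holstege4	0.02	0.98
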