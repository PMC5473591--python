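species	size_bp	pct_a	pct_g	pct_t	pct_c	pct_at	at_skew	gc_skew
S. sinensis	15905	37.4	9.4	38.3	14.9	75.7	-0.012	-0.228
H. latimera	16246	34.0	11.0	35.1	19.9	69.1	-0.017	-0.290
G. puia	15548	35.1	10.3	34.8	19.8	69.9	0.006	-0.313
P. sanguinolentus	16024	31.6	12.9	34.0	21.5	65.6	-0.037	-0.243
E. j. sinensis	16378	35.2	10.8	36.4	17.6	71.6	-0.016	-0.243
E. j. hepuensis	16335	35.1	10.8	36.4	17.7	71.5	-0.018	-0.245
E. j. japonica	16352	35.2	10.7	36.5	17.7	71.7	-0.018	-0.245
X. testudinatus	15798	36.7	9.3	37.2	16.8	73.9	-0.007	-0.297
P. gigas	15515	35.0	10.8	35.5	18.7	70.5	-0.006	-0.268
G. dehaani	18197	36.9	8.3	38.0	16.8	74.9	-0.014	-0.341
L. brevifrons	16112	34.2	11.3	36.4	18.1	70.6	-0.031	-0.231
C. sapidus	16263	34.2	11.1	34.9	19.8	69.1	-0.011	-0.279
P. trituberculatus	16026	33.3	11.3	36.9	18.5	70.2	-0.051	-0.241
H. malayensis	15793	37.3	10.0	34.4	18.3	71.7	0.040	-0.292
C. japonica	15738	33.8	11.9	35.4	18.9	69.2	-0.024	-0.228
S. paramamosain	15824	34.9	10.1	38.2	16.8	73.1	-0.045	-0.247
U. orientalis	15466	33.1	11.8	34.9	20.2	68.0	-0.027	-0.262
S. olivacea	15723	33.5	11.2	35.9	19.4	69.4	-0.035	-0.267
S. tranquebarica	15833	35.0	9.8	38.7	16.5	73.7	-0.050	-0.258
S. serrata	15775	34.5	10.4	38.0	17.1	72.5	-0.047	-0.242
D. spinosissimus	15817	33.3	10.5	36.8	19.4	70.1	-0.050	-0.294
C. feriata	15660	34.1	11.2	36.1	18.6	70.2	-0.028	-0.246
G. yunohana	15567	34.3	10.8	35.6	19.3	69.9	-0.019	-0.281
P. pelagicus	16157	33.7	12.2	35.0	19.1	68.8	-0.019	-0.219
A. alayseae	15620	34.4	11.4	32.4	21.8	66.8	0.029	-0.316
A. rodriguezensis	15611	35.3	10.3	33.5	20.9	68.8	0.025	-0.341
P. crassipes	15652	30.5	12.7	35.8	21.0	66.3	-0.080	-0.245
I. deschampsi	15460	34.1	10.7	35.5	19.7	69.6	-0.019	-0.294
O. cordimanus	15604	31.8	11.9	34.5	21.8	66.3	-0.043	-0.293
P. tripectinis	15612	36.2	10.1	38.0	15.7	74.2	-0.023	-0.215
M. japonicus	16170	33.6	10.9	32.8	22.7	66.4	0.014	-0.349
S. neglectum	15920	37.4	9.5	38.2	14.9	75.6	-0.010	-0.219
M. depressus	15765	37.9	8.7	39.4	14.0	77.3	-0.0038	-0.231
O. ceratophthalmus	15564	33.7	11.1	35.8	19.4	69.5	-0.029	-0.269
D. pilumnoides	16475	37.5	9.5	34.7	18.3	72.2	0.037	-0.316
M. majora	15903	38.4	9.8	35.5	16.3	73.9	0.039	-0.248
H. lichuanense	15380	35.8	9.3	37.4	17.5	73.2	-0.023	-0.305
M. fornasinii	15658	35.5	9.9	36.1	18.5	71.6	-0.0087	-0.303
C. granulosus	16300	33.2	11.2	36.1	19.5	69.3	-0.043	-0.272
M. longicarpus	15548	32.4	11.8	36.6	19.2	69.0	-0.060	-0.236
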