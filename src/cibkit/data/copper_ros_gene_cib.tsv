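# Published per-gene CIB values for copper-resistance and oxidative-stress
# (ROS) gene pairs: each row pairs a gene from a copper-bioleaching
# consortium strain with its homolog in the counterpart non-consortium
# strain of the same species.
block	gene_consortium	cib_consortium	gene_counterpart	cib_counterpart	name	cog
copper	LFPA_558	0.254	LFML04_RS04475	0.257	cutA	P
copper	ATLIC_3492	0.142	ATHIO_RS0103355	0.145		P
copper	STCUT_215	0.069	AOA63_RS11310	0.074	copA	P
copper	STCUT_220	0.093	AOA63_RS11335	0.100		P
copper	LFPA_1158	0.208	LFML04_RS01790	0.217		P
copper	ATLIC_2000	0.245	ATHIO_RS0110590	0.254		M,P
copper	ATLIC_1679	0.288	ATHIO_RS0112045	0.299	hmrR	K
copper	STCUT_1350	0.158	AOA63_RS16975	0.196		S
copper	AFWEN_2071	0.231	AFE_RS11165	0.278	cusA	V
copper	LFPA_601	0.148	LFML04_RS03050	0.216	cusA	V
copper	LFPA_601	0.148	LFML04_RS08675	0.224	cusA	V
copper	AMYEN_2455	0.250	ACMV_RS13835	0.521		P
ros	ATLIC_1147	0.332	ATHIO_RS0106580	0.333	sodA	P
ros	ATLIC_1534	0.188	ATHIO_RS0115785	0.196		O
ros	LFPA_122	0.167	LFML04_RS12970	0.176	resA	O,C
ros	LFPA_382	0.254	LFML04_RS05360	0.264	trxA	O,C
ros	ATLIC_2542	0.304	ATHIO_RS0105865	0.314		S
ros	LFPA_1163	0.227	LFML04_RS01815	0.237		O,C
ros	STCUT_347	0.284	AOA63_RS12055	0.295		S
ros	AFWEN_3145	0.259	AFE_RS01735	0.271		O
ros	AMYEN_133	0.392	ACMV_RS07445	0.406	trxA	O,C
ros	ATLIC_1449	0.140	ATHIO_RS0107230	0.155	msrA	O
ros	AMYEN_129	0.305	ACMV_RS07425	0.323	trxB	O
ros	ATLIC_1450	0.183	ATHIO_RS0107225	0.204	msrB	O
ros	AFWEN_2550	0.162	AFE_RS06860	0.184	bcp	O
ros	ATLIC_2479	0.201	ATHIO_RS0106370	0.227	bcp	O
ros	ATLIC_130	0.240	ATHIO_RS0108025	0.272	ahpC	O
ros	STCUT_838	0.130	AOA63_RS14385	0.163		O
ros	AFWEN_1580	0.267	AFE_RS13515	0.300	msrA	O
ros	STCUT_1306	0.178	AOA63_RS16755	0.223	sodA	P
ros	LFPA_1179	0.304	LFML04_RS01895	0.351	bcp	O
ros	STCUT_518	0.252	AOA63_RS12875	0.317	bcp	O
ros	LFPA_1314	0.244	LFML04_RS02930	0.316		O
ros	AFWEN_3137	0.162	AFE_RS01775	0.234	trxB	O
ros	ATLIC_589	0.246	ATHIO_RS0110035	0.319		O
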