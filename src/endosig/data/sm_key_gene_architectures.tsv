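# Curated PKS/NRPS key genes of the focal root-endophyte genome:
# curator-assigned class and ordered domain architecture per gene model.
gene_id	printed_class	architecture
PAC_02750	NRPS-like	A-T-R
PAC_02944	NRPS-like	A-T-R
PAC_01324	NRPS-like	A-T-R
PAC_02391	NRPS-like	A-T-R
PAC_03877	NRPS-like	A-T-R
PAC_04959	NRPS-like	A-T-R
PAC_05733	NRPS-like	A-T-R
PAC_07003	NRPS-like	A-T-R
PAC_12811	NRPS-like	A-T-R
PAC_17490	NRPS-like	A-T-R
PAC_19780	NRPS-like	A-T-R
PAC_02202	NRPS-like	A-T-R-Kinase
PAC_08842	NRPS-like	A-T-R-KR
PAC_08910	NRPS-like	A-T-TE
PAC_14584	NRPS-like	A-T-TE
PAC_19640	NRPS-like	A-T-DUF
PAC_12359	NRPS-like	A-T-DUF
PAC_05248	NRPS	A-T-C-A-T-C-A-T-C-T-C-T-C
PAC_13158	NRPS	A-T-C-A-T-C-T-C-A-T-C-T-C-T-C
PAC_15746	NRPS	A-T-C-T-C
PAC_20134	NRPS	C-A-T-C-A-T-C-A-T-C-A-T-C-T
PAC_16560	NRPS	A-T-C
PAC_16746	NRPS	A-T-C
PAC_19282	NRPS	A-T-C
PAC_02326	PKS-NRPS hybrid	KS-AT-DH-MT-KR-T-C-A-T-R
PAC_08246	PKS-NRPS hybrid	KS-AT-DH-MT-KR-T-C-A-T-R
PAC_01338	nonreducing type I PKS	SAT-KS-AT-PT-T-MT-TE
PAC_02435	nonreducing type I PKS	SAT-KS-AT-PT-T-MT-TE
PAC_03302	nonreducing type I PKS	KS-AT-DH-T-TE
PAC_03589	nonreducing type I PKS	KS-AT-PT-T-TE
PAC_07895	nonreducing type I PKS	SAT-KS-AT-PT-T-T-TE
PAC_08751	nonreducing type I PKS	SAT-KS-AT-PT-T-T-TE
PAC_10081	nonreducing type I PKS	SAT-KS-AT-PT-T-T-TE
PAC_11435	nonreducing type I PKS	SAT-KS-AT-PT-T-T-TE
PAC_00199	reducing type I PKS	KS-AT-DH-MT-ER-KR-T
PAC_00310	reducing type I PKS	KS-AT-DH-ER-KR-T
PAC_01646	reducing type I PKS	AT-DH-MT-ER-KR-T
PAC_04883	reducing type I PKS	KS-AT-DH-ER-KR-T
PAC_06141	reducing type I PKS	KS-AT-DH-ER-KR-T
PAC_10762	reducing type I PKS	KS-AT-DH-MT-ER-KR-T-Acyltransferase
PAC_11350	reducing type I PKS	KS-AT-DH-MT-ER-KR-T-Acyltransferase
PAC_14253	reducing type I PKS	KS-AT-DH-MT-ER-KR-T
PAC_14645	reducing type I PKS	KS-AT-DH-ER-KR-T
PAC_16276	reducing type I PKS	KS-AT-DH-MT-ER-KR-T-Acyltransferase
PAC_17799	reducing type I PKS	KS-AT-DH-ER-KR-T
PAC_19082	reducing type I PKS	KS-AT-DH-MT-ER-KR-T
PAC_19990	reducing type I PKS	KS-AT-DH-MT-KR-T-C
PAC_10712	reducing type I PKS	KS-AT-TH-KR-T
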