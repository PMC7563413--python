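navitoclax_targets	synthetic placeholder target set	TGT-0001	TGT-0002	TGT-0003	TGT-0004	TGT-0005	TGT-0006	TGT-0007	TGT-0008	TGT-0009	TGT-0010	TGT-0011	TGT-0012	TGT-0013	TGT-0014	TGT-0015	TGT-0016	TGT-0017	TGT-0018	TGT-0019	TGT-0020	TGT-0021	TGT-0022	TGT-0023	TGT-0024	TGT-0025	TGT-0026	TGT-0027	TGT-0028	TGT-0029	TGT-0030	TGT-0031	TGT-0032	TGT-0033	TGT-0034	TGT-0035	TGT-0036	TGT-0037	TGT-0038	TGT-0039	TGT-0040	TGT-0041	TGT-0042	TGT-0043	TGT-0044	TGT-0045	TGT-0046	TGT-0047	TGT-0048	TGT-0049	TGT-0050	TGT-0051	TGT-0052	TGT-0053	TGT-0054	TGT-0055	TGT-0056	TGT-0057	TGT-0058	TGT-0059	TGT-0060	TGT-0061	TGT-0062	TGT-0063	TGT-0064	TGT-0065	TGT-0066	TGT-0067	TGT-0068	TGT-0069	TGT-0070	TGT-0071	TGT-0072	TGT-0073	TGT-0074	TGT-0075	TGT-0076	TGT-0077	TGT-0078	TGT-0079	TGT-0080	TGT-0081
navitoclax_resistance	synthetic placeholder resistance set	RES-0001	RES-0002	RES-0003	RES-0004	RES-0005	RES-0006	RES-0007	RES-0008	RES-0009	RES-0010	RES-0011	RES-0012	RES-0013	RES-0014	RES-0015	RES-0016	RES-0017	RES-0018	RES-0019	RES-0020	RES-0021	RES-0022	RES-0023	RES-0024	RES-0025	RES-0026	RES-0027	RES-0028	RES-0029	RES-0030	RES-0031	RES-0032	RES-0033	RES-0034	RES-0035	RES-0036	RES-0037	RES-0038	RES-0039	RES-0040	RES-0041	RES-0042	RES-0043	RES-0044	RES-0045	RES-0046	RES-0047	RES-0048	RES-0049	RES-0050	RES-0051	RES-0052	RES-0053	RES-0054	RES-0055	RES-0056	RES-0057	RES-0058	RES-0059	RES-0060	RES-0061
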