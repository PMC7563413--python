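G1/S	synthetic placeholder phase program	CC-G1S-0001	CC-G1S-0002	CC-G1S-0003	CC-G1S-0004	CC-G1S-0005	CC-G1S-0006	CC-G1S-0007	CC-G1S-0008	CC-G1S-0009	CC-G1S-0010	CC-G1S-0011	CC-G1S-0012	CC-G1S-0013	CC-G1S-0014	CC-G1S-0015	CC-G1S-0016	CC-G1S-0017	CC-G1S-0018	CC-G1S-0019	CC-G1S-0020	CC-G1S-0021	CC-G1S-0022	CC-G1S-0023	CC-G1S-0024	CC-G1S-0025	CC-G1S-0026	CC-G1S-0027	CC-G1S-0028	CC-G1S-0029	CC-G1S-0030	CC-G1S-0031	CC-G1S-0032	CC-G1S-0033	CC-G1S-0034	CC-G1S-0035	CC-G1S-0036	CC-G1S-0037	CC-G1S-0038	CC-G1S-0039	CC-G1S-0040	CC-G1S-0041	CC-G1S-0042	CC-G1S-0043	CC-G1S-0044	CC-G1S-0045	CC-G1S-0046	CC-G1S-0047	CC-G1S-0048	CC-G1S-0049	CC-G1S-0050	CC-G1S-0051	CC-G1S-0052	CC-G1S-0053	CC-G1S-0054	CC-G1S-0055	CC-G1S-0056	CC-G1S-0057	CC-G1S-0058	CC-G1S-0059	CC-G1S-0060	CC-G1S-0061	CC-G1S-0062	CC-G1S-0063	CC-G1S-0064	CC-G1S-0065	CC-G1S-0066	CC-G1S-0067	CC-G1S-0068	CC-G1S-0069	CC-G1S-0070	CC-G1S-0071	CC-G1S-0072	CC-G1S-0073	CC-G1S-0074	CC-G1S-0075	CC-G1S-0076	CC-G1S-0077	CC-G1S-0078	CC-G1S-0079	CC-G1S-0080	CC-G1S-0081	CC-G1S-0082	CC-G1S-0083	CC-G1S-0084	CC-G1S-0085	CC-G1S-0086	CC-G1S-0087	CC-G1S-0088	CC-G1S-0089	CC-G1S-0090	CC-G1S-0091	CC-G1S-0092	CC-G1S-0093	CC-G1S-0094	CC-G1S-0095	CC-G1S-0096	CC-G1S-0097	CC-G1S-0098	CC-G1S-0099	CC-G1S-0100	CC-G1S-0101	CC-G1S-0102	CC-G1S-0103	CC-G1S-0104	CC-G1S-0105	CC-G1S-0106	CC-G1S-0107	CC-G1S-0108
S	synthetic placeholder phase program	CC-S-0001	CC-S-0002	CC-S-0003	CC-S-0004	CC-S-0005	CC-S-0006	CC-S-0007	CC-S-0008	CC-S-0009	CC-S-0010	CC-S-0011	CC-S-0012	CC-S-0013	CC-S-0014	CC-S-0015	CC-S-0016	CC-S-0017	CC-S-0018	CC-S-0019	CC-S-0020	CC-S-0021	CC-S-0022	CC-S-0023	CC-S-0024	CC-S-0025	CC-S-0026	CC-S-0027	CC-S-0028	CC-S-0029	CC-S-0030	CC-S-0031	CC-S-0032	CC-S-0033	CC-S-0034	CC-S-0035	CC-S-0036	CC-S-0037	CC-S-0038	CC-S-0039	CC-S-0040	CC-S-0041	CC-S-0042	CC-S-0043	CC-S-0044	CC-S-0045	CC-S-0046	CC-S-0047	CC-S-0048	CC-S-0049	CC-S-0050	CC-S-0051	CC-S-0052	CC-S-0053	CC-S-0054	CC-S-0055	CC-S-0056	CC-S-0057	CC-S-0058	CC-S-0059	CC-S-0060	CC-S-0061	CC-S-0062	CC-S-0063	CC-S-0064	CC-S-0065	CC-S-0066	CC-S-0067	CC-S-0068	CC-S-0069	CC-S-0070	CC-S-0071	CC-S-0072	CC-S-0073	CC-S-0074	CC-S-0075	CC-S-0076	CC-S-0077	CC-S-0078	CC-S-0079	CC-S-0080	CC-S-0081	CC-S-0082	CC-S-0083	CC-S-0084	CC-S-0085	CC-S-0086	CC-S-0087	CC-S-0088	CC-S-0089	CC-S-0090	CC-S-0091	CC-S-0092	CC-S-0093	CC-S-0094	CC-S-0095	CC-S-0096	CC-S-0097	CC-S-0098	CC-S-0099	CC-S-0100	CC-S-0101	CC-S-0102	CC-S-0103	CC-S-0104	CC-S-0105	CC-S-0106	CC-S-0107	CC-S-0108
G2	synthetic placeholder phase program	CC-G2-0001	CC-G2-0002	CC-G2-0003	CC-G2-0004	CC-G2-0005	CC-G2-0006	CC-G2-0007	CC-G2-0008	CC-G2-0009	CC-G2-0010	CC-G2-0011	CC-G2-0012	CC-G2-0013	CC-G2-0014	CC-G2-0015	CC-G2-0016	CC-G2-0017	CC-G2-0018	CC-G2-0019	CC-G2-0020	CC-G2-0021	CC-G2-0022	CC-G2-0023	CC-G2-0024	CC-G2-0025	CC-G2-0026	CC-G2-0027	CC-G2-0028	CC-G2-0029	CC-G2-0030	CC-G2-0031	CC-G2-0032	CC-G2-0033	CC-G2-0034	CC-G2-0035	CC-G2-0036	CC-G2-0037	CC-G2-0038	CC-G2-0039	CC-G2-0040	CC-G2-0041	CC-G2-0042	CC-G2-0043	CC-G2-0044	CC-G2-0045	CC-G2-0046	CC-G2-0047	CC-G2-0048	CC-G2-0049	CC-G2-0050	CC-G2-0051	CC-G2-0052	CC-G2-0053	CC-G2-0054	CC-G2-0055	CC-G2-0056	CC-G2-0057	CC-G2-0058	CC-G2-0059	CC-G2-0060	CC-G2-0061	CC-G2-0062	CC-G2-0063	CC-G2-0064	CC-G2-0065	CC-G2-0066	CC-G2-0067	CC-G2-0068	CC-G2-0069	CC-G2-0070	CC-G2-0071	CC-G2-0072	CC-G2-0073	CC-G2-0074	CC-G2-0075	CC-G2-0076	CC-G2-0077	CC-G2-0078	CC-G2-0079	CC-G2-0080	CC-G2-0081	CC-G2-0082	CC-G2-0083	CC-G2-0084	CC-G2-0085	CC-G2-0086	CC-G2-0087	CC-G2-0088	CC-G2-0089	CC-G2-0090	CC-G2-0091	CC-G2-0092	CC-G2-0093	CC-G2-0094	CC-G2-0095	CC-G2-0096	CC-G2-0097	CC-G2-0098	CC-G2-0099	CC-G2-0100	CC-G2-0101	CC-G2-0102	CC-G2-0103	CC-G2-0104	CC-G2-0105	CC-G2-0106	CC-G2-0107	CC-G2-0108
G2/M	synthetic placeholder phase program	CC-G2M-0001	CC-G2M-0002	CC-G2M-0003	CC-G2M-0004	CC-G2M-0005	CC-G2M-0006	CC-G2M-0007	CC-G2M-0008	CC-G2M-0009	CC-G2M-0010	CC-G2M-0011	CC-G2M-0012	CC-G2M-0013	CC-G2M-0014	CC-G2M-0015	CC-G2M-0016	CC-G2M-0017	CC-G2M-0018	CC-G2M-0019	CC-G2M-0020	CC-G2M-0021	CC-G2M-0022	CC-G2M-0023	CC-G2M-0024	CC-G2M-0025	CC-G2M-0026	CC-G2M-0027	CC-G2M-0028	CC-G2M-0029	CC-G2M-0030	CC-G2M-0031	CC-G2M-0032	CC-G2M-0033	CC-G2M-0034	CC-G2M-0035	CC-G2M-0036	CC-G2M-0037	CC-G2M-0038	CC-G2M-0039	CC-G2M-0040	CC-G2M-0041	CC-G2M-0042	CC-G2M-0043	CC-G2M-0044	CC-G2M-0045	CC-G2M-0046	CC-G2M-0047	CC-G2M-0048	CC-G2M-0049	CC-G2M-0050	CC-G2M-0051	CC-G2M-0052	CC-G2M-0053	CC-G2M-0054	CC-G2M-0055	CC-G2M-0056	CC-G2M-0057	CC-G2M-0058	CC-G2M-0059	CC-G2M-0060	CC-G2M-0061	CC-G2M-0062	CC-G2M-0063	CC-G2M-0064	CC-G2M-0065	CC-G2M-0066	CC-G2M-0067	CC-G2M-0068	CC-G2M-0069	CC-G2M-0070	CC-G2M-0071	CC-G2M-0072	CC-G2M-0073	CC-G2M-0074	CC-G2M-0075	CC-G2M-0076	CC-G2M-0077	CC-G2M-0078	CC-G2M-0079	CC-G2M-0080	CC-G2M-0081	CC-G2M-0082	CC-G2M-0083	CC-G2M-0084	CC-G2M-0085	CC-G2M-0086	CC-G2M-0087	CC-G2M-0088	CC-G2M-0089	CC-G2M-0090	CC-G2M-0091	CC-G2M-0092	CC-G2M-0093	CC-G2M-0094	CC-G2M-0095	CC-G2M-0096	CC-G2M-0097	CC-G2M-0098	CC-G2M-0099	CC-G2M-0100	CC-G2M-0101	CC-G2M-0102	CC-G2M-0103	CC-G2M-0104	CC-G2M-0105	CC-G2M-0106	CC-G2M-0107	CC-G2M-0108
M/G1	synthetic placeholder phase program	CC-MG1-0001	CC-MG1-0002	CC-MG1-0003	CC-MG1-0004	CC-MG1-0005	CC-MG1-0006	CC-MG1-0007	CC-MG1-0008	CC-MG1-0009	CC-MG1-0010	CC-MG1-0011	CC-MG1-0012	CC-MG1-0013	CC-MG1-0014	CC-MG1-0015	CC-MG1-0016	CC-MG1-0017	CC-MG1-0018	CC-MG1-0019	CC-MG1-0020	CC-MG1-0021	CC-MG1-0022	CC-MG1-0023	CC-MG1-0024	CC-MG1-0025	CC-MG1-0026	CC-MG1-0027	CC-MG1-0028	CC-MG1-0029	CC-MG1-0030	CC-MG1-0031	CC-MG1-0032	CC-MG1-0033	CC-MG1-0034	CC-MG1-0035	CC-MG1-0036	CC-MG1-0037	CC-MG1-0038	CC-MG1-0039	CC-MG1-0040	CC-MG1-0041	CC-MG1-0042	CC-MG1-0043	CC-MG1-0044	CC-MG1-0045	CC-MG1-0046	CC-MG1-0047	CC-MG1-0048	CC-MG1-0049	CC-MG1-0050	CC-MG1-0051	CC-MG1-0052	CC-MG1-0053	CC-MG1-0054	CC-MG1-0055	CC-MG1-0056	CC-MG1-0057	CC-MG1-0058	CC-MG1-0059	CC-MG1-0060	CC-MG1-0061	CC-MG1-0062	CC-MG1-0063	CC-MG1-0064	CC-MG1-0065	CC-MG1-0066	CC-MG1-0067	CC-MG1-0068	CC-MG1-0069	CC-MG1-0070	CC-MG1-0071	CC-MG1-0072	CC-MG1-0073	CC-MG1-0074	CC-MG1-0075	CC-MG1-0076	CC-MG1-0077	CC-MG1-0078	CC-MG1-0079	CC-MG1-0080	CC-MG1-0081	CC-MG1-0082	CC-MG1-0083	CC-MG1-0084	CC-MG1-0085	CC-MG1-0086	CC-MG1-0087	CC-MG1-0088	CC-MG1-0089	CC-MG1-0090	CC-MG1-0091	CC-MG1-0092	CC-MG1-0093	CC-MG1-0094	CC-MG1-0095	CC-MG1-0096	CC-MG1-0097	CC-MG1-0098	CC-MG1-0099	CC-MG1-0100	CC-MG1-0101	CC-MG1-0102	CC-MG1-0103	CC-MG1-0104	CC-MG1-0105	CC-MG1-0106	CC-MG1-0107	CC-MG1-0108
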