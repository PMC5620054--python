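species	clade	total_proteins	membrane_proteins	lhca_subset	metazoan_innovation	species_specific
H_sapiens	metazoan-vertebrate	20894	5797	4129	1668	53
M_musculus	metazoan-vertebrate	22627	7359	4731	2628	170
G_gallus	metazoan-vertebrate	16354	4461	3511	950	111
X_tropicalis	metazoan-vertebrate	18442	5773	4345	1428	34
D_rerio	metazoan-vertebrate	25638	7865	6054	1811	233
C_intestinalis	metazoan-invertebrate	16671	3542	2408	1134	649
S_purpuratus	metazoan-invertebrate	28842	7437	6082	990	0
D_melanogaster	metazoan-invertebrate	13918	3658	2653	1005	381
A_mellifera	metazoan-invertebrate	15314	2926	2215	711	1
A_pisum	metazoan-invertebrate	35189	5867	3492	2375	990
D_pulex	metazoan-invertebrate	30137	5243	3281	1962	1172
C_elegans	metazoan-invertebrate	20447	6788	3297	3491	1720
C_teleta	metazoan-invertebrate	32175	7968	5713	2255	910
L_anatina	metazoan-invertebrate	34105	8881	5891	2990	1120
C_gigas	metazoan-invertebrate	26092	6081	4507	1574	714
L_gigantea	metazoan-invertebrate	23675	5378	3806	1572	536
I_linei	metazoan-invertebrate	8720	1588	1328	260	255
S_mansoni	metazoan-invertebrate	10772	2576	1829	747	465
N_vectensis	metazoan-invertebrate	24773	5568	4496	1072	379
T_adhaerens	metazoan-invertebrate	11520	3146	2602	544	244
M_leidyi	metazoan-invertebrate	16548	4219	3064	1155	680
A_queenslandica	metazoan-invertebrate	29883	5861	4279	1582	760
M_brevicollis	outgroup	9196	2854	2108	0	502
C_owczarzaki	outgroup	8758	2543	2013	0	408
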