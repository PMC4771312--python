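# Published trait-depth summary (consenTRAIT tau_D mean/SD across bootstrap
# trees) for metal uptake traits in the Roseobacter and SAR11 lineages.
# Empty fields: the trait was not detected/scored in that lineage.
trait	substrate	roseobacter_mean	roseobacter_sd	sar11_mean	sar11_sd
afuA	Fe3+	0.0638	0.0040
PBP2_Fbp_like_1	Fe3+	0.0414	0.0020	0.0407	0.0017
PBP2_FutA1_like	Fe3+	0.0565	0.0068	0.1781	0.0091
hutB	heme	0.0274	0.0015
TBDT_MCL2	catecholate	0.0331	0.0015
fatB	catecholate	0.0363	0.0016
TBDT_MCL3	hydroxamate	0.0355	0.0015
fhuD	hydroxamate	0.0462	0.0021
SIP	siderophore_utilization	0.0476	0.0021
ZIP	Fe2+_Zn2+	0.0386	0.0028
znuA	Zn2+	0.0271	0.0024	0.0562	0.0021
psaA	Mn2+	0.0423	0.0056
troA_a	Mn2+_Zn2+	0.0263	0.0014
cbtA	Co2+	0.0307	0.0018
cbtB	Co2+	0.0346	0.0024
corA	Co2+_Ni2+_Mg2+	0.0400	0.0025	0.2785	0.0127
btuF	Co2+_as_B12			0.0809	0.0046
copZ	Cu_heavy_metals	0.0268	0.0013	0.0070	0.0010
TBDT_MCL5	unknown_multiple	0.0441	0.0025
total_TBDT	multiple	0.0493	0.0039	0.0652	0.0032
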