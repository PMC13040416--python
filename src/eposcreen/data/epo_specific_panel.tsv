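symbol	ncbi_symbol	biotype
AK2	AK2	protein_coding
ALAD	ALAD	protein_coding
AP2B1	AP2B1	protein_coding
ATP6V0A1	ATP6V0A1	protein_coding
BTRC	BTRC	protein_coding
CD247	CD247	protein_coding
CD28	CD28	protein_coding
CDK4	CDK4	protein_coding
COPS3	COPS3	protein_coding
CTSB	CTSB	protein_coding
DCAF10	DCAF10	protein_coding
DCAF11	DCAF11	protein_coding
DCTD	DCTD	protein_coding
DCTN4	DCTN4	protein_coding
DCUN1D1	DCUN1D1	protein_coding
DCUN1D4	DCUN1D4	protein_coding
E2F4	E2F4	protein_coding
FBXL4	FBXL4	protein_coding
FBXO30	FBXO30	protein_coding
FBXO9	FBXO9	protein_coding
FCHO2	FCHO2	protein_coding
ITSN1	ITSN1	protein_coding
JUN	JUN	protein_coding
KIF15	KIF15	protein_coding
LOC286444	RPS2P55	pseudogene
LOC389599	STRADBP1	pseudogene
LOC441455	MKRN10P	pseudogene
LOC100130562	RPS2P5	pseudogene
LOC100131164		pseudogene
MAPKAPK2	MAPKAPK2	protein_coding
MAPKAPK5	MAPKAPK5	protein_coding
MIF	MIF	protein_coding
MRS2	MRS2	protein_coding
NEDD4L	NEDD4L	protein_coding
NR3C1	NR3C1	protein_coding
PHC1	PHC1	protein_coding
PIK3R1	PIK3R1	protein_coding
PPM1A	PPM1A	protein_coding
PSENEN	PSENEN	protein_coding
PSMF1	PSMF1	protein_coding
RBBP4	RBBP4	protein_coding
RBL1	RBL1	protein_coding
SKAP1	SKAP1	protein_coding
SKI	SKI	protein_coding
SKP1	SKP1	protein_coding
TNRC6A	TNRC6A	protein_coding
TNRC6C	TNRC6C	protein_coding
UBA52	UBA52	protein_coding
UBE2F	UBE2F	protein_coding
UBQLN1	UBQLN1	protein_coding
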