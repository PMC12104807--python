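pathway	ko	gene_name	Xenacoelomorpha	Chordata	Protostomia
fly	K00910	GRK	1	1	1
fly	K02183	CALM	1	1	1
fly	K02677	PRKCA	1	1	1
fly	K04515	CaMKII	1	1	1
fly	K04547	GNG13	1	1	1
fly	K04634	GNAQ	1	1	1
fly	K04958	IP3R	1	1	1
fly	K04967	TRPC4	1	1	1
fly	K05692	ACTB_G1	1	1	1
fly	K05858	PLCB	1	1	1
fly	K07972	GNBh	0	0	1
fly	K08834	MYO3	1	1	1
fly	K13802	Rh1	0	0	1
fly	K13803	TRPL	1	0	1
fly	K13804	INAD	0	0	1
fly	K13805	ARR2	0	0	1
fly	K13806	DAGL	1	1	1
fly	K13807	PPEF/PPP7C	1	1	1
vertebrate	K00909	GRK1	0	1	0
vertebrate	K02183	CALM	1	1	1
vertebrate	K04250	RHO/OPN2	1	1	1
vertebrate	K04536	GNB1	1	1	1
vertebrate	K04548	GNGT1	0	1	0
vertebrate	K04631	GNAT1	0	1	0
vertebrate	K04948	CNGA1	0	1	1
vertebrate	K04952	CNGB1	0	1	1
vertebrate	K08328	GUCA1	1	1	1
vertebrate	K08718	PDE6A	0	1	0
vertebrate	K12321	GUCY2D_E	0	1	0
vertebrate	K12322	GUCY2F	0	1	1
vertebrate	K13749	SLC24A1/NCKX1	1	1	0
vertebrate	K13756	PDE6B	0	1	0
vertebrate	K13759	PDE6G	0	1	0
vertebrate	K13764	RCVRN	0	1	0
vertebrate	K13765	RGS9	0	1	1
vertebrate	K19627	SAG	0	1	0
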