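rice_locus_id	arabidopsis_locus_id	description	mutant_stock	homozygous	photosynthesis
LOC_Os01g72800	AT2G45770	CPFTSY, chloroplast SRP receptor alpha subunit; required for LHCP integration into thylakoids	SALK_070410C	1	1
LOC_Os01g72950	AT1G74880	NDH-O, subunit of the thylakoid NAD(P)H:plastoquinone dehydrogenase (Ndh) complex	SALK_097351C	1	1
LOC_Os03g02590	AT1G01820	PEROXIN11C, peroxisome membrane protein controlling peroxisome proliferation	SALK_057358C	1	0
LOC_Os03g03910	AT4G35090	CAT2, catalase 2	SALK_076998	1	0
LOC_Os03g19760	AT1G56500	SOQ1, suppressor of quenching 1; maintains light-harvesting efficiency	SALK_097577	0	1
LOC_Os03g36750	AT3G48420	Haloacid dehalogenase-like hydrolase (HAD) superfamily protein	SALK_025204	1	0
LOC_Os03g52460	AT5G19220	APL1, large subunit of ADP-glucose pyrophosphorylase (starch biosynthesis)	CS478981	1	0
LOC_Os05g33520	AT2G48070	RPH1, chloroplast protein involved in immune response	SALK_102558C	1	0
LOC_Os07g37550	AT5G54270	LHCB3, component of the main light-harvesting chlorophyll a/b complex of photosystem II	SALK_020314C	1	1
LOC_Os07g38300	AT3G63190	RRF, chloroplast ribosome recycling factor homolog	SALK_015954C	1	1
LOC_Os08g16570	AT1G16080	Nuclear protein	SALK_007790C	1	0
LOC_Os08g41040	AT4G31115	DUF1997 family protein	SALK_010690C	1	0
LOC_Os08g41460	AT4G11960	PGRL1B, thylakoid transmembrane protein; loss perturbs cyclic electron flow	SALK_059238C	1	1
LOC_Os08g41460	AT4G22890	PGRL1A, thylakoid transmembrane protein; loss perturbs cyclic electron flow	SALK_133856C	1	1
LOC_Os09g10750	AT2G42220	Rhodanese/cell cycle control phosphatase superfamily protein	SALK_045769	1	0
LOC_Os09g39390	AT2G27680	NAD(P)-linked oxidoreductase superfamily protein	SALK_073120C	1	1
LOC_Os10g10170	AT4G34830	MRL1, pentatricopeptide repeat protein required for rbcL mRNA stabilization	SALK_060806C	1	1
LOC_Os11g43600	AT3G62910	CPRF1, plastid ribosome release factor 1 essential for chloroplast development	SALK_117765C	0	0
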