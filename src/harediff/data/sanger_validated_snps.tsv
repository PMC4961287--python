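gene	position	ref	alt	european_rnaseq	anatolian_rnaseq	european_sanger	anatolian_sanger
UQCRC2	1218	C	T	C	C/T	C	C
UQCRC2	1234	G	A	G	G/A	G	G
UQCRC2	1263	C	T	C	C/T	C	C
NDUFB5	54	G	A	G	G/A	G	G
NDUFB5	55	C	T	C	T	C	C
NDUFB5	56	G	C	G	C	G	G
NDUFB5	91	G	A	G	A	G	G
ATP5G1	178	T	A	A/T	T	A/T	T
ATP5H	556	A	C/G	A/G	A/C	A	A
NDUFA4	218	G	A	G	G/A	G	G
NDUFS2	70	G	T	G/T	G	G	G
EPRS	1258	A	G	G/A	G	G/A	G
RARS	242	G	A	G/A	G	G	G
RARS	280	C	T	C/T	C	C	C
RARS	312	A	G	A/G	A	A/G	G
DARS2	334	G	A	G	G/A	G	A
DARS2	554	A	C	A	A/C	A/C	A/C
DARS2	1405	G	A	G	G/A	G	A
DARS2	1600	A	G	A	A/G	A	A
ATP5J2	275	G	A	G/A	G	G/A	G/A
ATP5J2	465	C	A	C/A	A	C/A	A
ATP5J2	474	T	C	T/C	T	T/C	T/C
ETFA	139	G	C	G	G/C	G/C	G/C
NDUFAF7	1145	A	C	A/C	A/C	A/C	A
NDUFAF7	1215	G	T	G	G/T	G	G
NDUFAF7	1248	G	A	G/A	G/A	G/A	G
NDUFAF1	32	C	T	C/T	C	C/T	C
NDUFAF1	67	C	G	C/G	C	C/G	C
NDUFAF1	91	C	T	C/T	C	C	C
NDUFB6	386	A	G	A/G	A	A	A
NDUFV2	519	A	G	A/G	A/G	A/G	A
OXA1L	111	G	A	G/A	G	G/A	G
OXA1L	122	G	A	G/A	G	G/A	G/A
OXA1L	145	G	C	G	G/C	G	G
SCO1	409	G	A	G/A	G	G	G
SCO1	800	A	T	A/T	A	A	A
SCO1	804	C	T	C	C/T	C	C
SDHD	91	G	A	G/A	G	T/G	G
SDHD	93	C	T	C/T	C	C/T	C
SDHD	157	C	T	C/T	C	A/C/T	C/T
TFAM	315	A	T	A	A/T	A	A
TFAM	371	G	C	G/C	G/C	G/C	G
SARS2	487	T	C	T/C	C	T/C	C
FARS2	140	G	A	G/A	G	G	G
FARS2	663	G	C	G/C	G	G/C	G
FARS2	680	A	G	A	A/G	A	A
FARS2	693	G	A	A/G	A/G	A/G	G
FARS2	708	T	C	T/C	T/C	T/C	T
FARS2	756	A	G	A/G	A/G	G	A
LARS2	2434	G	A	G	G/A	G	G
LARS2	2489	T	C	T/C	C	T/C	C
LARS2	2509	G	C	G	G/C	G	G
LARS	1085	T	C	T/C	T	C	T
COX5B	356	A	G	A/G	A/G	A	G
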