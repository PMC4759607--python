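# rCRS (NC_012920) locus map: 1-based inclusive coordinates; DLOOP wraps the origin.
# frame_offset: codon phase of `start` within the locus's own reading frame (coding loci only).
name	start	end	strand	category	frame_offset
DLOOP	16024	576	heavy	DLOOP	0
MTTF	577	647	heavy	tRNA	0
MTRNR1	648	1601	heavy	rRNA	0
MTTV	1602	1670	heavy	tRNA	0
MTRNR2	1671	3229	heavy	rRNA	0
MTTL1	3230	3304	heavy	tRNA	0
MTND1	3307	4262	heavy	coding	0
MTTI	4263	4331	heavy	tRNA	0
MTTQ	4329	4400	light	tRNA	0
MTTM	4402	4469	heavy	tRNA	0
MTND2	4470	5511	heavy	coding	0
MTTW	5512	5579	heavy	tRNA	0
MTTA	5587	5655	light	tRNA	0
MTTN	5657	5729	light	tRNA	0
MTTC	5761	5826	light	tRNA	0
MTTY	5826	5891	light	tRNA	0
MTCO1	5904	7445	heavy	coding	0
MTTS1	7446	7514	light	tRNA	0
MTTD	7518	7585	heavy	tRNA	0
MTCO2	7586	8269	heavy	coding	0
MTTK	8295	8364	heavy	tRNA	0
MTATP8	8366	8572	heavy	coding	0
MTATP6	8527	9207	heavy	coding	0
MTCO3	9207	9990	heavy	coding	0
MTTG	9991	10058	heavy	tRNA	0
MTND3	10059	10404	heavy	coding	0
MTTR	10405	10469	heavy	tRNA	0
MTND4L	10470	10766	heavy	coding	0
MTND4	10760	12137	heavy	coding	0
MTTH	12138	12206	heavy	tRNA	0
MTTS2	12207	12265	heavy	tRNA	0
MTTL2	12266	12336	heavy	tRNA	0
MTND5	12337	14148	heavy	coding	0
MTND6	14149	14673	light	coding	0
MTTE	14674	14742	light	tRNA	0
MTCYB	14747	15887	heavy	coding	0
MTTT	15888	15953	heavy	tRNA	0
MTTP	15956	16023	light	tRNA	0
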