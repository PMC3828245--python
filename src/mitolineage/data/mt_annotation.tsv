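gene	start	end	type	strand
CR	1	576	noncoding	+
TRNF	577	647	trna	+
RNR1	648	1601	rrna	+
TRNV	1602	1670	trna	+
RNR2	1671	3229	rrna	+
TRNL1	3230	3304	trna	+
ND1	3307	4262	coding	+
TRNI	4263	4331	trna	+
TRNQ	4329	4400	trna	-
TRNM	4402	4469	trna	+
ND2	4470	5511	coding	+
TRNW	5512	5579	trna	+
TRNA	5587	5655	trna	-
TRNN	5657	5729	trna	-
OL	5730	5760	noncoding	+
TRNC	5761	5826	trna	-
TRNY	5826	5891	trna	-
CO1	5904	7445	coding	+
TRNS1	7446	7514	trna	-
TRND	7518	7585	trna	+
CO2	7586	8269	coding	+
TRNK	8295	8364	trna	+
ATP8	8366	8572	coding	+
ATP6	8527	9207	coding	+
CO3	9207	9990	coding	+
TRNG	9991	10058	trna	+
ND3	10059	10404	coding	+
TRNR	10405	10469	trna	+
ND4L	10470	10766	coding	+
ND4	10760	12137	coding	+
TRNH	12138	12206	trna	+
TRNS2	12207	12265	trna	+
TRNL2	12266	12336	trna	+
ND5	12337	14148	coding	+
ND6	14149	14673	coding	-
TRNE	14674	14742	trna	-
CYB	14747	15887	coding	+
TRNT	15888	15953	trna	+
TRNP	15956	16023	trna	-
CR	16024	16569	noncoding	+
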