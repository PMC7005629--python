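name	synonyms	locus_type	segments	strand
D-loop	control region;MT-DLOOP	D_loop	16024-16569;1-576	heavy
MT-TF	TRNF;tRNA-Phe	tRNA	577-647	heavy
MT-RNR1	RNR1;12S rRNA;MTRNR1	rRNA	648-1601	heavy
MT-TV	TRNV;tRNA-Val	tRNA	1602-1670	heavy
MT-RNR2	RNR2;16S rRNA;MTRNR2	rRNA	1671-3229	heavy
MT-TL1	TRNL1;tRNA-Leu(UUR)	tRNA	3230-3304	heavy
MT-ND1	ND1;NADH dehydrogenase subunit 1	protein_coding	3307-4262	heavy
MT-TI	TRNI;tRNA-Ile	tRNA	4263-4331	heavy
MT-TQ	TRNQ;tRNA-Gln	tRNA	4329-4400	light
MT-TM	TRNM;tRNA-Met	tRNA	4402-4469	heavy
MT-ND2	ND2;NADH dehydrogenase subunit 2	protein_coding	4470-5511	heavy
MT-TW	TRNW;tRNA-Trp	tRNA	5512-5579	heavy
MT-TA	TRNA;tRNA-Ala	tRNA	5587-5655	light
MT-TN	TRNN;tRNA-Asn	tRNA	5657-5729	light
MT-TC	TRNC;tRNA-Cys	tRNA	5761-5826	light
MT-TY	TRNY;tRNA-Tyr	tRNA	5826-5891	light
MT-CO1	COX1;COI;cytochrome c oxidase subunit I	protein_coding	5904-7445	heavy
MT-TS1	TRNS1;tRNA-Ser(UCN)	tRNA	7446-7514	light
MT-TD	TRND;tRNA-Asp	tRNA	7518-7585	heavy
MT-CO2	COX2;COII;cytochrome c oxidase subunit II	protein_coding	7586-8269	heavy
MT-TK	TRNK;tRNA-Lys	tRNA	8295-8364	heavy
MT-ATP8	ATP8;ATPase8;ATP synthase F0 subunit 8	protein_coding	8366-8572	heavy
MT-ATP6	ATP6;ATPase6;ATP synthase F0 subunit 6	protein_coding	8527-9207	heavy
MT-CO3	COX3;COIII;cytochrome c oxidase subunit III	protein_coding	9207-9990	heavy
MT-TG	TRNG;tRNA-Gly	tRNA	9991-10058	heavy
MT-ND3	ND3;NADH dehydrogenase subunit 3	protein_coding	10059-10404	heavy
MT-TR	TRNR;tRNA-Arg	tRNA	10405-10469	heavy
MT-ND4L	ND4L;NADH dehydrogenase subunit 4L	protein_coding	10470-10766	heavy
MT-ND4	ND4;NADH dehydrogenase subunit 4	protein_coding	10760-12137	heavy
MT-TH	TRNH;tRNA-His	tRNA	12138-12206	heavy
MT-TS2	TRNS2;tRNA-Ser(AGY)	tRNA	12207-12265	heavy
MT-TL2	TRNL2;tRNA-Leu(CUN)	tRNA	12266-12336	heavy
MT-ND5	ND5;NADH dehydrogenase subunit 5	protein_coding	12337-14148	heavy
MT-ND6	ND6;NADH dehydrogenase subunit 6	protein_coding	14149-14673	light
MT-TE	TRNE;tRNA-Glu	tRNA	14674-14742	light
MT-CYB	CYTB;cytochrome b	protein_coding	14747-15887	heavy
MT-TT	TRNT;tRNA-Thr	tRNA	15888-15953	heavy
MT-TP	TRNP;tRNA-Pro	tRNA	15956-16023	light
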