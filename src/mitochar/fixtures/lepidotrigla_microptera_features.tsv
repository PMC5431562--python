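feature	category	strand	start	end	start_codon	stop_codon	anticodon
tRNA-Phe (F)	tRNA	H	1	68
12S rRNA	rRNA	H	69	1109
tRNA-Val (V)	tRNA	H	1110	1181
16S rRNA	rRNA	H	1182	2876
tRNA-Leu (UUR)	tRNA	H	2877	2950
ND1	PCG	H	2951	3925	ATG	TAA
tRNA-Ile (I)	tRNA	H	3930	3999
tRNA-Gln (Q)	tRNA	L	4000	4070
tRNA-Met (M)	tRNA	H	4070	4138
ND2	PCG	H	4139	5185	ATG	TTA
tRNA-Trp (W)	tRNA	H	5185	5255
tRNA-Ala (A)	tRNA	L	5257	5325
tRNA-Asn (N)	tRNA	L	5327	5399
O_L	OL	L	5400	5437
tRNA-Cys (C)	tRNA	L	5438	5502
tRNA-Tyr (Y)	tRNA	L	5503	5572
COX1	PCG	H	5574	7124	GTG	TAA
tRNA-Ser (UCN)	tRNA	L	7125	7195
tRNA-Asp (D)	tRNA	H	7199	7271
COX2	PCG	H	7292	7983	ATG	T
tRNA-Lys (K)	tRNA	H	7984	8057
ATPase 8	PCG	H	8059	8266	ATG	T
ATPase 6	PCG	H	8217	8900	ATG	TAA
COX3	PCG	H	8900	9685	ATG	TAA
tRNA-Gly (G)	tRNA	H	9685	9756
ND3	PCG	H	9757	10107	ATG	TAG
tRNA-Arg (R)	tRNA	H	10106	10174
ND4L	PCG	H	10175	10471	ATG	TAA
ND4	PCG	H	10465	11845	ATG	T
tRNA-His (H)	tRNA	H	11846	11914
tRNA-Ser (AGN)	tRNA	H	11915	11982
tRNA-Leu (CUN)	tRNA	H	11987	12059
ND5	PCG	H	12060	13898	ATG	TAG
ND6	PCG	L	13895	14416	ATG	TAA
tRNA-Glu (E)	tRNA	L	14417	14485
CytB	PCG	H	14491	15631	ATG	T
tRNA-Thr (T)	tRNA	H	15632	15703
tRNA-Pro (P)	tRNA	L	15703	15772
Control region	CR	H	15773	16610
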