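feature	category	strand	start	end	start_codon	stop_codon	anticodon
tRNA-Phe (F)	tRNA	H	1	68
12S rRNA	rRNA	H	69	1011
tRNA-Val (V)	tRNA	H	1015	1086
16S rRNA	rRNA	H	1087	2799
tRNA-Leu (UUR)	tRNA	H	2780	2854
ND1	PCG	H	2855	3829	ATG	TAA
tRNA-Ile (I)	tRNA	H	3834	3903
tRNA-Gln (Q)	tRNA	L	3903	3973
tRNA-Met (M)	tRNA	H	3973	4041
ND2	PCG	H	4042	5087	ATG	TTA
tRNA-Trp (W)	tRNA	H	5088	5158
tRNA-Ala (A)	tRNA	L	5160	5228
tRNA-Asn (N)	tRNA	L	5230	5302
O_L	OL	L	5303	5338
tRNA-Cys (C)	tRNA	L	5339	5405
tRNA-Tyr (Y)	tRNA	L	5406	5475
COX1	PCG	H	5477	7027	GTG	TAA
tRNA-Ser (UCN)	tRNA	L	7028	7098
tRNA-Asp (D)	tRNA	H	7102	7174
COX2	PCG	H	7181	7871	ATG	T
tRNA-Lys (K)	tRNA	H	7872	7945
ATPase 8	PCG	H	7947	8114	ATG	TAA
ATPase 6	PCG	H	8105	8788	ATG	TAA
COX3	PCG	H	8788	9570	ATG	TAA
tRNA-Gly (G)	tRNA	H	9570	9641
ND3	PCG	H	9642	9992	ATG	TAG
tRNA-Arg (R)	tRNA	H	9991	10059
ND4L	PCG	H	10060	10356	ATG	TAA
ND4	PCG	H	10350	11731	ATG	T
tRNA-His (H)	tRNA	H	11731	11799
tRNA-Ser (AGN)	tRNA	H	11800	11867
tRNA-Leu (CUN)	tRNA	H	11872	11944
ND5	PCG	H	11945	13783	ATG	TAA
ND6	PCG	L	13780	14301	ATG	TAA
tRNA-Glu (E)	tRNA	L	14302	14370
CytB	PCG	H	14376	15516	ATG	T
tRNA-Thr (T)	tRNA	H	15517	15588
tRNA-Pro (P)	tRNA	L	15588	15657
Control region	CR	H	15658	16495
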