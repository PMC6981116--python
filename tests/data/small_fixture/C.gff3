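##gff-version 3
##sequence-region chr01 1 274700
##sequence-region chr02 1 125675
chr01	paleokaryo-sim	gene	2131	4704	.	-	.	ID=C_g00001
chr01	paleokaryo-sim	gene	6825	8160	.	+	.	ID=C_g00002
chr01	paleokaryo-sim	gene	10549	12279	.	-	.	ID=C_g00003
chr01	paleokaryo-sim	gene	16508	18373	.	-	.	ID=C_g00004
chr01	paleokaryo-sim	gene	21389	23123	.	-	.	ID=C_g00005
chr01	paleokaryo-sim	gene	27400	28447	.	+	.	ID=C_g00006
chr01	paleokaryo-sim	gene	35715	38203	.	-	.	ID=C_g00007
chr01	paleokaryo-sim	gene	40495	42548	.	-	.	ID=C_g00008
chr01	paleokaryo-sim	gene	47595	50347	.	+	.	ID=C_g00009
chr01	paleokaryo-sim	gene	55972	58512	.	+	.	ID=C_g00010
chr01	paleokaryo-sim	gene	64452	65781	.	-	.	ID=C_g00011
chr01	paleokaryo-sim	gene	68474	69895	.	+	.	ID=C_g00012
chr01	paleokaryo-sim	gene	75354	76694	.	+	.	ID=C_g00013
chr01	paleokaryo-sim	gene	84517	87236	.	-	.	ID=C_g00014
chr01	paleokaryo-sim	gene	92979	95652	.	+	.	ID=C_g00015
chr01	paleokaryo-sim	gene	102665	103913	.	-	.	ID=C_g00016
chr01	paleokaryo-sim	gene	106120	107511	.	-	.	ID=C_g00017
chr01	paleokaryo-sim	gene	109866	110987	.	-	.	ID=C_g00018
chr01	paleokaryo-sim	gene	113418	114599	.	-	.	ID=C_g00019
chr01	paleokaryo-sim	gene	116997	119829	.	-	.	ID=C_g00020
chr01	paleokaryo-sim	gene	125581	126959	.	-	.	ID=C_g00021
chr01	paleokaryo-sim	gene	132679	134454	.	-	.	ID=C_g00022
chr01	paleokaryo-sim	gene	137648	140604	.	+	.	ID=C_g00023
chr01	paleokaryo-sim	gene	142699	143604	.	+	.	ID=C_g00024
chr01	paleokaryo-sim	gene	149321	152171	.	+	.	ID=C_g00025
chr01	paleokaryo-sim	gene	154453	155497	.	+	.	ID=C_g00026
chr01	paleokaryo-sim	gene	162882	164820	.	-	.	ID=C_g00027
chr01	paleokaryo-sim	gene	167786	169963	.	-	.	ID=C_g00028
chr01	paleokaryo-sim	gene	174122	176468	.	-	.	ID=C_g00029
chr01	paleokaryo-sim	gene	182055	184565	.	+	.	ID=C_g00030
chr01	paleokaryo-sim	gene	191881	193200	.	+	.	ID=C_g00031
chr01	paleokaryo-sim	gene	201019	202209	.	+	.	ID=C_g00032
chr01	paleokaryo-sim	gene	204261	205399	.	-	.	ID=C_g00033
chr01	paleokaryo-sim	gene	209072	210638	.	+	.	ID=C_g00034
chr01	paleokaryo-sim	gene	215717	217927	.	+	.	ID=C_g00035
chr01	paleokaryo-sim	gene	224839	227000	.	-	.	ID=C_g00036
chr01	paleokaryo-sim	gene	230585	231674	.	-	.	ID=C_g00037
chr01	paleokaryo-sim	gene	236713	239703	.	-	.	ID=C_g00038
chr01	paleokaryo-sim	gene	246274	247279	.	-	.	ID=C_g00039
chr01	paleokaryo-sim	gene	251396	254242	.	+	.	ID=C_g00040
chr01	paleokaryo-sim	gene	261355	263378	.	-	.	ID=C_g00041
chr01	paleokaryo-sim	gene	266427	269094	.	+	.	ID=C_g00042
chr01	paleokaryo-sim	gene	272050	273700	.	+	.	ID=C_g00043
chr02	paleokaryo-sim	gene	6295	7202	.	-	.	ID=C_g00044
chr02	paleokaryo-sim	gene	9234	11479	.	+	.	ID=C_g00045
chr02	paleokaryo-sim	gene	18811	21652	.	+	.	ID=C_g00046
chr02	paleokaryo-sim	gene	28635	30522	.	-	.	ID=C_g00047
chr02	paleokaryo-sim	gene	32815	34995	.	+	.	ID=C_g00048
chr02	paleokaryo-sim	gene	38820	40702	.	-	.	ID=C_g00049
chr02	paleokaryo-sim	gene	48218	51132	.	-	.	ID=C_g00050
chr02	paleokaryo-sim	gene	57945	59236	.	-	.	ID=C_g00051
chr02	paleokaryo-sim	gene	65531	66989	.	+	.	ID=C_g00052
chr02	paleokaryo-sim	gene	74218	75824	.	-	.	ID=C_g00053
chr02	paleokaryo-sim	gene	83166	84454	.	-	.	ID=C_g00054
chr02	paleokaryo-sim	gene	86655	88028	.	-	.	ID=C_g00055
chr02	paleokaryo-sim	gene	94178	96424	.	-	.	ID=C_g00056
chr02	paleokaryo-sim	gene	102741	104587	.	+	.	ID=C_g00057
chr02	paleokaryo-sim	gene	109810	111685	.	+	.	ID=C_g00058
chr02	paleokaryo-sim	gene	115143	117483	.	+	.	ID=C_g00059
chr02	paleokaryo-sim	gene	122988	124675	.	-	.	ID=C_g00060
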