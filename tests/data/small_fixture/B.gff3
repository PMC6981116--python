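##gff-version 3
##sequence-region chr01 1 408177
chr01	paleokaryo-sim	gene	3411	5061	.	-	.	ID=B_g00001
chr01	paleokaryo-sim	gene	8667	11334	.	-	.	ID=B_g00002
chr01	paleokaryo-sim	gene	13896	15919	.	+	.	ID=B_g00003
chr01	paleokaryo-sim	gene	19274	22120	.	-	.	ID=B_g00004
chr01	paleokaryo-sim	gene	24875	25880	.	+	.	ID=B_g00005
chr01	paleokaryo-sim	gene	28382	31372	.	+	.	ID=B_g00006
chr01	paleokaryo-sim	gene	34755	35844	.	+	.	ID=B_g00007
chr01	paleokaryo-sim	gene	38945	41106	.	+	.	ID=B_g00008
chr01	paleokaryo-sim	gene	45077	47287	.	-	.	ID=B_g00009
chr01	paleokaryo-sim	gene	54952	56817	.	-	.	ID=B_g00010
chr01	paleokaryo-sim	gene	60850	62584	.	-	.	ID=B_g00011
chr01	paleokaryo-sim	gene	68007	69054	.	+	.	ID=B_g00012
chr01	paleokaryo-sim	gene	74967	77455	.	-	.	ID=B_g00013
chr01	paleokaryo-sim	gene	81265	83318	.	-	.	ID=B_g00014
chr01	paleokaryo-sim	gene	87921	90673	.	+	.	ID=B_g00015
chr01	paleokaryo-sim	gene	94979	97519	.	+	.	ID=B_g00016
chr01	paleokaryo-sim	gene	104260	105589	.	-	.	ID=B_g00017
chr01	paleokaryo-sim	gene	109089	110819	.	+	.	ID=B_g00018
chr01	paleokaryo-sim	gene	114656	115991	.	-	.	ID=B_g00019
chr01	paleokaryo-sim	gene	118990	121563	.	+	.	ID=B_g00020
chr01	paleokaryo-sim	gene	124370	126245	.	+	.	ID=B_g00021
chr01	paleokaryo-sim	gene	132910	135250	.	+	.	ID=B_g00022
chr01	paleokaryo-sim	gene	142402	144089	.	-	.	ID=B_g00023
chr01	paleokaryo-sim	gene	147964	148869	.	-	.	ID=B_g00024
chr01	paleokaryo-sim	gene	151056	154012	.	-	.	ID=B_g00025
chr01	paleokaryo-sim	gene	161992	163767	.	+	.	ID=B_g00026
chr01	paleokaryo-sim	gene	170170	171548	.	+	.	ID=B_g00027
chr01	paleokaryo-sim	gene	174640	177472	.	+	.	ID=B_g00028
chr01	paleokaryo-sim	gene	182703	183884	.	+	.	ID=B_g00029
chr01	paleokaryo-sim	gene	191335	192456	.	+	.	ID=B_g00030
chr01	paleokaryo-sim	gene	199626	201017	.	+	.	ID=B_g00031
chr01	paleokaryo-sim	gene	207897	209145	.	+	.	ID=B_g00032
chr01	paleokaryo-sim	gene	214533	217206	.	-	.	ID=B_g00033
chr01	paleokaryo-sim	gene	223535	226254	.	+	.	ID=B_g00034
chr01	paleokaryo-sim	gene	228438	229778	.	-	.	ID=B_g00035
chr01	paleokaryo-sim	gene	232940	234361	.	-	.	ID=B_g00036
chr01	paleokaryo-sim	gene	240532	242098	.	-	.	ID=B_g00037
chr01	paleokaryo-sim	gene	245593	246731	.	+	.	ID=B_g00038
chr01	paleokaryo-sim	gene	248736	249926	.	-	.	ID=B_g00039
chr01	paleokaryo-sim	gene	254828	257174	.	-	.	ID=B_g00040
chr01	paleokaryo-sim	gene	263311	265821	.	+	.	ID=B_g00041
chr01	paleokaryo-sim	gene	273250	274569	.	+	.	ID=B_g00042
chr01	paleokaryo-sim	gene	278350	279808	.	-	.	ID=B_g00043
chr01	paleokaryo-sim	gene	285476	286767	.	+	.	ID=B_g00044
chr01	paleokaryo-sim	gene	292931	295845	.	+	.	ID=B_g00045
chr01	paleokaryo-sim	gene	303766	305648	.	+	.	ID=B_g00046
chr01	paleokaryo-sim	gene	310617	312797	.	-	.	ID=B_g00047
chr01	paleokaryo-sim	gene	319461	321348	.	+	.	ID=B_g00048
chr01	paleokaryo-sim	gene	326320	329161	.	-	.	ID=B_g00049
chr01	paleokaryo-sim	gene	333875	336120	.	-	.	ID=B_g00050
chr01	paleokaryo-sim	gene	342078	342985	.	+	.	ID=B_g00051
chr01	paleokaryo-sim	gene	350246	353096	.	+	.	ID=B_g00052
chr01	paleokaryo-sim	gene	359160	360204	.	+	.	ID=B_g00053
chr01	paleokaryo-sim	gene	365057	366995	.	-	.	ID=B_g00054
chr01	paleokaryo-sim	gene	373026	375203	.	-	.	ID=B_g00055
chr01	paleokaryo-sim	gene	382733	384339	.	-	.	ID=B_g00056
chr01	paleokaryo-sim	gene	392153	393441	.	-	.	ID=B_g00057
chr01	paleokaryo-sim	gene	396375	398221	.	-	.	ID=B_g00058
chr01	paleokaryo-sim	gene	400909	403155	.	+	.	ID=B_g00059
chr01	paleokaryo-sim	gene	405804	407177	.	+	.	ID=B_g00060
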