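##gff-version 3
##sequence-region chr01 1 192668
##sequence-region chr02 1 236677
chr01	paleokaryo-sim	gene	7879	9252	.	-	.	ID=A_g00001
chr01	paleokaryo-sim	gene	15073	17319	.	-	.	ID=A_g00002
chr01	paleokaryo-sim	gene	24620	26466	.	+	.	ID=A_g00003
chr01	paleokaryo-sim	gene	28938	30226	.	+	.	ID=A_g00004
chr01	paleokaryo-sim	gene	35157	36763	.	+	.	ID=A_g00005
chr01	paleokaryo-sim	gene	42758	44935	.	+	.	ID=A_g00006
chr01	paleokaryo-sim	gene	51952	53890	.	+	.	ID=A_g00007
chr01	paleokaryo-sim	gene	60029	61073	.	-	.	ID=A_g00008
chr01	paleokaryo-sim	gene	67758	70608	.	-	.	ID=A_g00009
chr01	paleokaryo-sim	gene	76078	76985	.	-	.	ID=A_g00010
chr01	paleokaryo-sim	gene	82827	85072	.	+	.	ID=A_g00011
chr01	paleokaryo-sim	gene	91499	94340	.	+	.	ID=A_g00012
chr01	paleokaryo-sim	gene	98119	99454	.	+	.	ID=A_g00013
chr01	paleokaryo-sim	gene	104312	106042	.	-	.	ID=A_g00014
chr01	paleokaryo-sim	gene	109968	111534	.	-	.	ID=A_g00015
chr01	paleokaryo-sim	gene	116469	117607	.	+	.	ID=A_g00016
chr01	paleokaryo-sim	gene	122981	124171	.	-	.	ID=A_g00017
chr01	paleokaryo-sim	gene	130874	132193	.	-	.	ID=A_g00018
chr01	paleokaryo-sim	gene	139759	142269	.	-	.	ID=A_g00019
chr01	paleokaryo-sim	gene	150016	152362	.	+	.	ID=A_g00020
chr01	paleokaryo-sim	gene	159507	160965	.	-	.	ID=A_g00021
chr01	paleokaryo-sim	gene	167410	168701	.	+	.	ID=A_g00022
chr01	paleokaryo-sim	gene	172459	175373	.	+	.	ID=A_g00023
chr01	paleokaryo-sim	gene	182162	184044	.	+	.	ID=A_g00024
chr01	paleokaryo-sim	gene	189488	191668	.	-	.	ID=A_g00025
chr02	paleokaryo-sim	gene	2961	4848	.	+	.	ID=A_g00026
chr02	paleokaryo-sim	gene	10638	13211	.	+	.	ID=A_g00027
chr02	paleokaryo-sim	gene	19998	21873	.	+	.	ID=A_g00028
chr02	paleokaryo-sim	gene	24881	27221	.	+	.	ID=A_g00029
chr02	paleokaryo-sim	gene	30743	32430	.	-	.	ID=A_g00030
chr02	paleokaryo-sim	gene	38140	39045	.	-	.	ID=A_g00031
chr02	paleokaryo-sim	gene	41375	44331	.	-	.	ID=A_g00032
chr02	paleokaryo-sim	gene	46774	48549	.	+	.	ID=A_g00033
chr02	paleokaryo-sim	gene	53192	54570	.	+	.	ID=A_g00034
chr02	paleokaryo-sim	gene	60668	63500	.	+	.	ID=A_g00035
chr02	paleokaryo-sim	gene	69787	70968	.	+	.	ID=A_g00036
chr02	paleokaryo-sim	gene	77213	78334	.	+	.	ID=A_g00037
chr02	paleokaryo-sim	gene	80755	82146	.	+	.	ID=A_g00038
chr02	paleokaryo-sim	gene	84250	85498	.	+	.	ID=A_g00039
chr02	paleokaryo-sim	gene	90838	93511	.	-	.	ID=A_g00040
chr02	paleokaryo-sim	gene	96195	98914	.	+	.	ID=A_g00041
chr02	paleokaryo-sim	gene	103898	105238	.	-	.	ID=A_g00042
chr02	paleokaryo-sim	gene	107572	108993	.	-	.	ID=A_g00043
chr02	paleokaryo-sim	gene	114826	116155	.	+	.	ID=A_g00044
chr02	paleokaryo-sim	gene	121555	124095	.	-	.	ID=A_g00045
chr02	paleokaryo-sim	gene	128258	131010	.	-	.	ID=A_g00046
chr02	paleokaryo-sim	gene	135063	137116	.	+	.	ID=A_g00047
chr02	paleokaryo-sim	gene	144462	146950	.	+	.	ID=A_g00048
chr02	paleokaryo-sim	gene	153733	154780	.	-	.	ID=A_g00049
chr02	paleokaryo-sim	gene	162311	164045	.	+	.	ID=A_g00050
chr02	paleokaryo-sim	gene	169670	171535	.	+	.	ID=A_g00051
chr02	paleokaryo-sim	gene	175057	177267	.	+	.	ID=A_g00052
chr02	paleokaryo-sim	gene	182473	184634	.	-	.	ID=A_g00053
chr02	paleokaryo-sim	gene	187825	188914	.	-	.	ID=A_g00054
chr02	paleokaryo-sim	gene	195002	197992	.	-	.	ID=A_g00055
chr02	paleokaryo-sim	gene	205549	206554	.	-	.	ID=A_g00056
chr02	paleokaryo-sim	gene	212133	214979	.	+	.	ID=A_g00057
chr02	paleokaryo-sim	gene	222106	224129	.	-	.	ID=A_g00058
chr02	paleokaryo-sim	gene	229104	231771	.	+	.	ID=A_g00059
chr02	paleokaryo-sim	gene	234027	235677	.	+	.	ID=A_g00060
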