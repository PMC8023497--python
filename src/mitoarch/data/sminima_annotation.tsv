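# Annotation of the Siliqua minima mitogenome (GenBank MT375556), 17,064 bp,
# circular; all 36 genes on the heavy strand. Coordinates 1-based inclusive.
gene	category	strand	start	end	anticodon
cox1	PCG	+	1	1569
trnL2	tRNA	+	1578	1643	TAA
nad1	PCG	+	1641	2579
trnL1	tRNA	+	2579	2645	TAG
trnV	tRNA	+	2650	2714	TAC
trnN	tRNA	+	2716	2782	GTT
nad5	PCG	+	2846	4543
cytb	PCG	+	4582	5727
nad6	PCG	+	5786	6286
rrnL	rRNA	+	6276	7522
atp6	PCG	+	7514	8212
trnM	tRNA	+	8219	8285	CAT
rrnS	rRNA	+	8390	9218
cox3	PCG	+	9217	10005
trnS1	tRNA	+	10005	10071	TCT
nad2	PCG	+	10111	11127
trnK	tRNA	+	12499	12563	TTT
cox2	PCG	+	12598	13282
trnY	tRNA	+	13550	13612	GTA
nad4l	PCG	+	13616	13903
trnG	tRNA	+	13903	13967	TCC
trnP	tRNA	+	13973	14037	TGG
nad4	PCG	+	14204	15517
trnH	tRNA	+	15539	15601	GTG
trnW	tRNA	+	15616	15681	TCA
trnR	tRNA	+	15682	15746	TCG
trnE	tRNA	+	15748	15823	TTC
trnS2	tRNA	+	15808	15870	TGA
nad3	PCG	+	15883	16236
trnT	tRNA	+	16237	16304	TGT
trnI	tRNA	+	16305	16369	GAT
trnD	tRNA	+	16373	16438	GTC
trnQ	tRNA	+	16449	16516	TTG
trnC	tRNA	+	16532	16596	GCA
trnA	tRNA	+	16600	16664	TGC
trnF	tRNA	+	16726	16790	GAA
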