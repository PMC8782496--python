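chrom	arm	start	end
1	p	1	121535434
1	q	124535435	249250621
2	p	1	92326171
2	q	95326172	243199373
3	p	1	90504854
3	q	93504855	198022430
4	p	1	49660117
4	q	52660118	191154276
5	p	1	46405641
5	q	49405642	180915260
6	p	1	58830166
6	q	61830167	171115067
7	p	1	58054331
7	q	61054332	159138663
8	p	1	43838887
8	q	46838888	146364022
9	p	1	47367679
9	q	50367680	141213431
10	p	1	39254935
10	q	42254936	135534747
11	p	1	51644205
11	q	54644206	135006516
12	p	1	34856694
12	q	37856695	133851895
13	p	1	16000000
13	q	19000001	115169878
14	p	1	16000000
14	q	19000001	107349540
15	p	1	17000000
15	q	20000001	102531392
16	p	1	35335801
16	q	38335802	90354753
17	p	1	22263006
17	q	25263007	81195210
18	p	1	15460898
18	q	18460899	78077248
19	p	1	24681782
19	q	27681783	59128983
20	p	1	26369569
20	q	29369570	63025520
21	p	1	11288129
21	q	14288130	48129895
22	p	1	13000000
22	q	16000001	51304566
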