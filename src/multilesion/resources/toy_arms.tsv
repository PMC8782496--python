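chrom	arm	start	end
1	p	1	500000
1	q	500001	1000000
2	p	1	400000
2	q	400001	800000
3	p	1	300000
3	q	300001	600000
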