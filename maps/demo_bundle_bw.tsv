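chain	res_seq	res_name	bw
A	101	ALA	1.43
A	102	ALA	1.44
A	103	LEU	1.45
A	104	ALA	1.46
A	105	ALA	1.47
A	106	ALA	1.48
A	107	LEU	1.49
A	108	ALA	1.50
A	109	ALA	1.51
A	110	ALA	1.52
A	111	LEU	1.53
A	112	ALA	1.54
A	113	ALA	1.55
A	114	ALA	1.56
A	115	LEU	1.57
A	116	ALA	1.58
A	201	ALA	2.43
A	202	ALA	2.44
A	203	LEU	2.45
A	204	ASP	2.46
A	205	ALA	2.47
A	206	ALA	2.48
A	207	LEU	2.49
A	208	ALA	2.50
A	209	ALA	2.51
A	210	ALA	2.52
A	211	LEU	2.53
A	212	ALA	2.54
A	213	ALA	2.55
A	214	ALA	2.56
A	215	LEU	2.57
A	216	ALA	2.58
A	301	ALA	3.43
A	302	ALA	3.44
A	303	LEU	3.45
A	304	ARG	3.46
A	305	ALA	3.47
A	306	ALA	3.48
A	307	LEU	3.49
A	308	ARG	3.50
A	309	ALA	3.51
A	310	ALA	3.52
A	311	LEU	3.53
A	312	ALA	3.54
A	313	ALA	3.55
A	314	ALA	3.56
A	315	LEU	3.57
A	316	ALA	3.58
A	401	ALA	4.43
A	402	ALA	4.44
A	403	LEU	4.45
A	404	ALA	4.46
A	405	ALA	4.47
A	406	ALA	4.48
A	407	LEU	4.49
A	408	GLU	4.50
A	409	ALA	4.51
A	410	ALA	4.52
A	411	LEU	4.53
A	412	ALA	4.54
A	413	ALA	4.55
A	414	ALA	4.56
A	415	LEU	4.57
A	416	ALA	4.58
A	501	ALA	5.43
A	502	ALA	5.44
A	503	LEU	5.45
A	504	ALA	5.46
A	505	ALA	5.47
A	506	ALA	5.48
A	507	LEU	5.49
A	508	ALA	5.50
A	509	ALA	5.51
A	510	SER	5.52
A	511	LEU	5.53
A	512	ALA	5.54
A	513	ALA	5.55
A	514	ALA	5.56
A	515	LEU	5.57
A	516	ALA	5.58
A	601	ALA	6.43
A	602	ALA	6.44
A	603	LEU	6.45
A	604	ALA	6.46
A	605	LEU	6.47
A	606	ALA	6.48
A	607	LEU	6.49
A	608	ALA	6.50
A	609	ALA	6.51
A	610	ASP	6.52
A	611	LEU	6.53
A	612	ALA	6.54
A	613	ALA	6.55
A	614	ALA	6.56
A	615	LEU	6.57
A	616	ALA	6.58
A	701	ALA	7.43
A	702	ALA	7.44
A	703	LEU	7.45
A	704	ALA	7.46
A	705	ILE	7.47
A	706	ALA	7.48
A	707	LEU	7.49
A	708	ALA	7.50
A	709	ALA	7.51
A	710	ALA	7.52
A	711	LEU	7.53
A	712	ALA	7.54
A	713	ALA	7.55
A	714	ALA	7.56
A	715	LEU	7.57
A	716	ALA	7.58
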