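chain	res_seq	res_name	bw
A	573	UNK	1.37
A	574	UNK	1.38
A	575	UNK	1.39
A	576	UNK	1.40
A	577	UNK	1.41
A	578	UNK	1.42
A	579	UNK	1.43
A	580	UNK	1.44
A	581	UNK	1.45
A	582	UNK	1.46
A	583	UNK	1.47
A	584	UNK	1.48
A	585	UNK	1.49
A	586	UNK	1.50
A	587	UNK	1.51
A	588	UNK	1.52
A	589	UNK	1.53
A	590	UNK	1.54
A	591	UNK	1.55
A	592	UNK	1.56
A	593	UNK	1.57
A	594	UNK	1.58
A	595	UNK	1.59
A	596	UNK	1.60
A	597	UNK	1.61
A	598	UNK	1.62
A	599	UNK	1.63
A	600	UNK	1.64
A	606	UNK	2.37
A	607	UNK	2.38
A	608	UNK	2.39
A	609	UNK	2.40
A	610	UNK	2.41
A	611	UNK	2.42
A	612	UNK	2.43
A	613	UNK	2.44
A	614	UNK	2.45
A	615	UNK	2.46
A	616	UNK	2.47
A	617	UNK	2.48
A	618	UNK	2.49
A	619	UNK	2.50
A	620	UNK	2.51
A	621	UNK	2.52
A	622	UNK	2.53
A	623	UNK	2.54
A	624	UNK	2.55
A	625	UNK	2.56
A	626	UNK	2.57
A	627	UNK	2.58
A	628	UNK	2.59
A	629	UNK	2.60
A	630	UNK	2.61
A	631	UNK	2.62
A	632	UNK	2.63
A	633	UNK	2.64
A	640	UNK	3.32
A	641	UNK	3.33
A	642	UNK	3.34
A	643	UNK	3.35
A	644	UNK	3.36
A	645	UNK	3.37
A	646	UNK	3.38
A	647	UNK	3.39
A	648	UNK	3.40
A	649	UNK	3.41
A	650	UNK	3.42
A	651	UNK	3.43
A	652	UNK	3.44
A	653	UNK	3.45
A	654	UNK	3.46
A	655	UNK	3.47
A	656	UNK	3.48
A	657	UNK	3.49
A	658	UNK	3.50
A	659	UNK	3.51
A	660	UNK	3.52
A	661	UNK	3.53
A	662	UNK	3.54
A	663	UNK	3.55
A	664	UNK	3.56
A	665	UNK	3.57
A	666	UNK	3.58
A	667	UNK	3.59
A	668	UNK	3.60
A	669	UNK	3.61
A	676	UNK	4.38
A	677	UNK	4.39
A	678	UNK	4.40
A	679	UNK	4.41
A	680	UNK	4.42
A	681	UNK	4.43
A	682	UNK	4.44
A	683	UNK	4.45
A	684	UNK	4.46
A	685	UNK	4.47
A	686	UNK	4.48
A	687	UNK	4.49
A	688	UNK	4.50
A	689	UNK	4.51
A	690	UNK	4.52
A	691	UNK	4.53
A	692	UNK	4.54
A	693	UNK	4.55
A	694	UNK	4.56
A	695	UNK	4.57
A	696	UNK	4.58
A	697	UNK	4.59
A	698	UNK	4.60
A	699	UNK	4.61
A	700	UNK	4.62
A	706	UNK	5.33
A	707	UNK	5.34
A	708	UNK	5.35
A	709	UNK	5.36
A	710	UNK	5.37
A	711	UNK	5.38
A	712	UNK	5.39
A	713	UNK	5.40
A	714	UNK	5.41
A	715	UNK	5.42
A	716	UNK	5.43
A	717	UNK	5.44
A	718	UNK	5.45
A	719	UNK	5.46
A	720	UNK	5.47
A	721	UNK	5.48
A	722	UNK	5.49
A	723	UNK	5.50
A	724	UNK	5.51
A	725	UNK	5.52
A	726	UNK	5.53
A	727	UNK	5.54
A	728	UNK	5.55
A	729	UNK	5.56
A	730	UNK	5.57
A	731	UNK	5.58
A	732	UNK	5.59
A	733	UNK	5.60
A	742	UNK	6.35
A	743	UNK	6.36
A	744	UNK	6.37
A	745	UNK	6.38
A	746	UNK	6.39
A	747	UNK	6.40
A	748	UNK	6.41
A	749	UNK	6.42
A	750	UNK	6.43
A	751	UNK	6.44
A	752	UNK	6.45
A	753	UNK	6.46
A	754	UNK	6.47
A	755	UNK	6.48
A	756	UNK	6.49
A	757	UNK	6.50
A	758	UNK	6.51
A	759	UNK	6.52
A	760	UNK	6.53
A	761	UNK	6.54
A	762	UNK	6.55
A	763	UNK	6.56
A	764	UNK	6.57
A	765	UNK	6.58
A	766	UNK	6.59
A	767	UNK	6.60
A	768	UNK	6.61
A	769	UNK	6.62
A	770	UNK	6.63
A	771	UNK	6.64
A	776	UNK	7.23
A	777	UNK	7.24
A	778	UNK	7.25
A	779	UNK	7.26
A	780	UNK	7.27
A	781	UNK	7.28
A	782	UNK	7.29
A	783	UNK	7.30
A	784	UNK	7.31
A	785	UNK	7.32
A	786	UNK	7.33
A	787	UNK	7.34
A	788	UNK	7.35
A	789	UNK	7.36
A	790	UNK	7.37
A	791	UNK	7.38
A	792	UNK	7.39
A	793	UNK	7.40
A	794	UNK	7.41
A	795	UNK	7.42
A	796	UNK	7.43
A	797	UNK	7.44
A	798	UNK	7.45
A	799	UNK	7.46
A	800	UNK	7.47
A	801	UNK	7.48
A	802	UNK	7.49
A	803	UNK	7.50
A	804	UNK	7.51
A	805	UNK	7.52
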