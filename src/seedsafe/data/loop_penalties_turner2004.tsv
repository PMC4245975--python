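# Loop-size initiation penalties, RNA, 37 C, Turner 2004 set.
# Units: dcal/mol.  "inf" = size not allowed.  Sizes above 30 are extrapolated
# at run time with the Jacobson-Stockmayer term dG(n) = dG(30) + lxc*ln(n/30).
size	hairpin	bulge	internal
0	inf	inf	inf
1	inf	380	inf
2	inf	280	100
3	540	320	100
4	560	360	110
5	570	400	200
6	540	440	200
7	600	460	210
8	550	470	230
9	640	480	240
10	650	490	250
11	660	500	260
12	670	510	270
13	680	520	280
14	690	530	290
15	690	540	290
16	700	540	300
17	710	550	310
18	710	550	310
19	720	560	320
20	720	570	330
21	730	570	330
22	730	580	340
23	740	580	340
24	740	580	350
25	750	590	350
26	750	590	350
27	750	600	360
28	760	600	360
29	760	600	370
30	770	610	370
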