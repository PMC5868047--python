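position,carbon_of,delta_C,delta_N,delta_H,mult,J,nH
1-N,,,78.9,,,,0
2,,174.0,,,,,0
3-N,,,241.7,,,,0
4,,156.0,,,,,0
5,,117.8,,7.17,d,8.5,1
6,,129.4,,7.31,dd,8.4;2.0,1
7,,126.3,,,,,0
8,,123.8,,6.95,bs,,1
9,,133.3,,,,,0
10,,58.9,,,,,0
11,,54.8,,5.02,dd,10.8;4.7,1
12a,12,52.6,,3.87,dd,13.3;6.6,1
12b,12,,,3.66,dd,13.3;10.5,1
13-N,,,87.5,,,,0
14,,159.1,,,,,0
15-N,,,216.6,,,,0
16,,143.9,,,,,0
17,,124.2,,6.94,d,8.2,1
18,,127.2,,7.12,dd,8.2;2.4,1
19,,125.8,,,,,0
20,,127.3,,6.96,s,,1
21,,125.4,,,,,0
22a,22,29.6,,2.48,d,15.9,1
22b,22,,,2.28,d,15.9,1
23,,39.8,,,,,0
24a,24,24.7,,2.25,m,,1
24b,24,,,1.73,dd,15.0;6.2,1
25a,25,47.4,,3.38,ddd,12.5;7.5;1.6,1
25b,25,,,3.18,dt,11.7;5.9,1
26,,37.2,,3.0,s,,3
27,,35.8,,3.24,s,,3
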