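position,atom_index
1-N,0
10,9
11,10
12,11
12a,34
12b,35
13-N,12
14,13
15-N,14
16,15
17,16
18,17
19,18
2,1
20,19
21,20
22,21
22a,40
22b,39
23,22
24,23
24a,41
24b,42
25,24
25a,43
25b,44
26,25
27,26
3-N,2
4,3
5,4
6,5
7,6
8,7
9,8
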