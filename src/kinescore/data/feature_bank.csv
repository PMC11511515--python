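feature_id,kind,i,v,j,m,n
1,angular,2,5,13,,
2,angular,1,6,14,,
3,angular,3,10,8,,
4,angular,4,11,9,,
5,angular,6,16,11,,
6,angular,5,16,10,,
7,angular,5,16,11,,
8,angular,6,16,10,,
9,angular,11,16,10,,
10,angular,6,12,5,,
11,angular,2,12,1,,
12,angular,3,16,4,,
13,angular,2,16,3,,
14,angular,1,16,4,,
15,angular,2,16,4,,
16,angular,1,16,3,,
17,angular,5,12,16,,
18,angular,6,12,16,,
19,angular,10,16,12,,
20,angular,11,16,12,,
21,angular,2,12,16,,
22,angular,1,12,16,,
23,angular,3,16,12,,
24,angular,4,16,12,,
25,angular,12,5,1,,
26,angular,12,6,2,,
27,nddi,1,,4,2,3
28,nddi,1,,2,4,3
29,nddi,6,,11,5,10
30,nddi,6,,5,11,10
31,nddi,5,,10,7,16
32,nddi,6,,11,7,16
33,nddi,2,,10,7,16
34,nddi,1,,11,7,16
35,nddi,2,,3,7,16
36,nddi,1,,4,7,16
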