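acquisition,patient,normalized_by_mean,normalized_by_median
1,1,181,184
2,1,171,175
3,1,184,193
4,1,187,193
5,1,191,199
6,1,174,175
7,1,174,181
8,1,189,190
9,1,171,173
10,2,173,179
11,2,171,185
12,2,182,187
13,2,176,186
14,2,175,186
15,2,168,168
16,2,176,184
17,3,178,182
18,3,178,180
19,3,180,179
20,3,182,183
21,3,176,176
22,3,182,183
23,3,180,180
24,3,176,175
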