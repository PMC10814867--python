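y,age,bmi,glucose
0,31,22.4,88
1,52,31.7,148
0,27,24.1,95
0,44,26.9,110
1,61,35.2,165
0,38,23.8,101
0,29,21.5,84
1,57,33.0,152
0,46,27.4,117
0,33,25.0,99
1,49,30.1,141
0,25,20.9,79
0,41,28.3,122
1,66,34.6,171
0,36,24.7,104
0,30,22.0,90
1,54,32.2,158
0,43,26.1,113
0,28,23.2,93
0,39,25.8,107
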