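# minimal diagram of 9_1^2: one crossing per line
# over_arc under_in_arc under_out_arc sign comp_over comp_under
4 0 1 1 0 0
7 4 0 1 1 0
0 7 8 1 0 1
1 6 7 -1 0 1
6 1 2 -1 1 0
2 5 6 -1 0 1
5 2 3 -1 1 0
3 8 5 -1 0 1
8 3 4 -1 1 0
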