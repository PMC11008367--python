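# minimal diagram of 8_2^2: one crossing per line
# over_arc under_in_arc under_out_arc sign comp_over comp_under
3 7 4 -1 0 1
4 3 0 -1 1 0
0 6 7 -1 0 1
6 0 1 -1 1 0
1 5 6 -1 0 1
5 1 2 -1 1 0
2 4 5 -1 0 1
7 2 3 -1 1 0
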