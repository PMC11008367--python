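# minimal diagram of 6_2^2: one crossing per line
# over_arc under_in_arc under_out_arc sign comp_over comp_under
2 5 3 -1 0 1
3 2 0 -1 1 0
0 4 5 -1 0 1
4 0 1 -1 1 0
1 3 4 -1 0 1
5 1 2 -1 1 0
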