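# minimal diagram of 2_1^2: one crossing per line
# over_arc under_in_arc under_out_arc sign comp_over comp_under
0 1 1 -1 0 1
1 0 0 -1 1 0
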