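# noiseless events for the sequence ACGTACGT under pore_model_k2.tsv
# 2-mers: AC CG GT TA AC CG GT -> states 1 6 11 12 1 6 11 -> levels below
55
80
105
110
55
80
105
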