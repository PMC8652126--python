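gene_a,gene_b,partial_correlation
g3,g7,-0.857142857142857
g4,g6,0.857142857142857
g5,g8,-0.857142857142857
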