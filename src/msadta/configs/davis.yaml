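# Shipped defaults for the Davis kinase benchmark (pKd affinities)
l_d: 36
l_p: 900
e_d: 64
e_p: 64
n_heads: 4
window_sizes: [0, 1, 2, 3]
L_d: 2
L_p: 1
ffn_hidden: [1024, 1024, 512, 1]
dropout: 0.1
learning_rate: 0.0001
epochs: 300
batch_size: 32
aggregation: flatten
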