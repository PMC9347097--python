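# Shipped defaults for the KIBA kinase-inhibitor benchmark
l_d: 80
l_p: 800
e_d: 128
e_p: 128
n_heads: 4
window_sizes: [0, 1, 2, 3]
L_d: 2
L_p: 2
ffn_hidden: [1024, 1024, 512, 1]
dropout: 0.1
learning_rate: 0.0001
epochs: 300
batch_size: 32
aggregation: flatten
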