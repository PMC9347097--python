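# Desk-scale configuration for synthetic data and CPU-only runs
l_d: 16
l_p: 16
e_d: 16
e_p: 16
n_heads: 4
window_sizes: [0, 1, 2, 3]
L_d: 1
L_p: 1
ffn_hidden: [1024, 1024, 512, 1]
dropout: 0.1
learning_rate: 0.0001
epochs: 50
batch_size: 8
aggregation: flatten
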