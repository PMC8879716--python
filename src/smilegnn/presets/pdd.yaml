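# preset tuned for the dense, structure-rich regime
batch_size: 1024
learning_rate: 0.01
embed_dim: 64
d_struct: 64
aggregator_type: concat
fusion_method: concat
n_hops: 2
sample_size: 8
epochs: 50
n_folds: 5
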