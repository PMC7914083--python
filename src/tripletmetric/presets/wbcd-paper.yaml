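# Full-scale cytology-table settings, shipped for fidelity: lr 0.001,
# batch 16, momentum 0.3, weight decay 0.0004.
seed: 0
outer_iters: 160
inner_batches: 16
metric_steps: 5
lr_w: 0.001
lr_M: 0.001
momentum: 0.3
weight_decay: 0.0004
batch_K: 2
batch_L: 8       # batch of K*L = 16 samples
margin: 1.0
balance_mu: 0.1
rounds: 2
preset: desk
input_size: 64
enhance: false
classifier_head: centroid
use_attention: false
average_metric_tail: false
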