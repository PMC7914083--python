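# Desk-scale defaults: CPU-minute training on 64x64 synthetic images.
seed: 0
outer_iters: 20
inner_batches: 16
metric_steps: 5
lr_w: 0.02
lr_M: 0.01
momentum: 0.5
weight_decay: 0.0
batch_K: 2
batch_L: 8
margin: 0.2
balance_mu: 0.5
rounds: 2
preset: desk
input_size: 64
enhance: false
classifier_head: centroid
use_attention: false
average_metric_tail: false
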