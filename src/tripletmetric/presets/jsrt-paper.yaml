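# Full-scale chest-radiograph settings, shipped for fidelity: initial lr
# 0.01 (decayed x0.1 at epochs 50 and 80 when driven by an epoch schedule),
# 160 epochs, batch 128, plain SGD (no momentum stated).  Running this
# preset requires the external 2048x2048 radiograph data and GPU-scale
# compute; it is not exercised by the desk-scale tests.
seed: 0
outer_iters: 160
inner_batches: 16
metric_steps: 5
lr_w: 0.01
lr_M: 0.01
momentum: 0.0
weight_decay: 0.0
batch_K: 2
batch_L: 64      # batch of K*L = 128 samples
margin: 1.0
balance_mu: 0.1
rounds: 2
preset: paper
input_size: 2048
enhance: true
classifier_head: centroid
use_attention: false
average_metric_tail: false
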