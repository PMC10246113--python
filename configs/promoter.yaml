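# Conditional promoter-like sequence design at full scale: 1024-bp
# TSS-centered sequences with per-position initiation-signal
# conditioning (synthetic generator stands in for a real CAGE-derived
# dataset). Large-compute configuration.
task: promoter-synthetic
seed: 0
length: 1024
batch_size: 128
lr: 1.0e-3
n_steps: 100000
net_options:
  width: 128
  n_blocks: 12
cache_n_per_cell: 10000
cache_steps_per_unit: 1000
sampler_n_steps: 400
time_dilation: 4
out_dir: runs/promoter
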