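# Desk-scale 4x4 Sudoku pipeline (CPU, ~10 min): trains the relational
# transformer residual around the factorized mixture baseline.
task: mini-sudoku
seed: 0
batch_size: 96
lr: 2.5e-3
n_steps: 8000
time_window: [0.12, 3.0]
net_options:
  n_blocks: 3
  d_model: 48
  heads: 4
cache_n_per_cell: 800
cache_steps_per_unit: 400
sampler_n_steps: 160
time_dilation: 4
out_dir: runs/mini_sudoku
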