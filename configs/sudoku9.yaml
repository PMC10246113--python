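# Full 9x9 Sudoku generation/solving. This is the large-compute
# configuration: expect multi-day training on CPU; a GPU-backed array
# library would be needed to reach the reported-accuracy regime.
task: sudoku
seed: 0
batch_size: 256
lr: 1.0e-3
n_steps: 200000
time_window: [0.12, 3.0]
net_options:
  n_blocks: 20
  d_model: 96
  heads: 4
cache_n_per_cell: 10000
cache_steps_per_unit: 1000
sampler_n_steps: 400
time_dilation: 8
out_dir: runs/sudoku9
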