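# Demo configuration for `ramanscreen run-all --config examples/run.yaml`.
# Fields mirror ramanscreen.pipeline.RunConfig; omitted fields use defaults
# (full 1 cm^-1 grid, 100x >70 stability selection, 50x 70/30 hold-out).
n_per_group: {healthy: 10, benign: 10, cancer: 10}
n_external_per_group: {healthy: 3, benign: 3, cancer: 3}
grid_step: 4.0
selection: {n_repeats: 50, min_hits: 35}
classifier: {C_grid: [1.0, 10.0, 100.0], gamma_grid: [0.01, 0.1]}
split: {n_repeats: 10}
external_model_repeats: 3
out_dir: ramanscreen_run
seed: 0
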