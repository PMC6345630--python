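# Thin/normal/fat strain family dividing at a fixed surface area,
# the wild-type condition.
seed: 7
output_dir: area-sizer-run
strains: presets
division_rule: {kind: area, threshold: 165.0}
n_cells: 500
n_bins: 10
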