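# Full synthetic study: two Kesten cohorts, annotations and masks.
# Run with:  synmorph run --config examples/synthetic_config.yaml
output_dir: results/pipeline_demo
seed: 1
n_boot: 200
intervals: [30, 60, 120]
synthetic:
  EE:
    n_spines: 400
  Ctr:
    n_spines: 400
synthetic_annotations:
  EE:
    30: [0.20, 0.40, 0.40]
    60: [0.20, 0.40, 0.40]
    120: [0.20, 0.35, 0.45]
  Ctr:
    30: [0.40, 0.40, 0.20]
    60: [0.25, 0.40, 0.35]
    120: [0.10, 0.35, 0.55]
synthetic_masks:
  EE: {macular: 9, perforated: 4, clustered: 7}
  Ctr: {macular: 9, perforated: 6, clustered: 5}
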