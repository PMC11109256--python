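# YAML configuration schema

`dla run --config experiment.yaml` (or `dlanet.pipeline.RunConfig.from_yaml`)
drives the full pipeline. All keys are optional; omitted keys take the
defaults shown. A locked copy (`config.lock.yaml`) is written into every
run directory and reproduces the run exactly.

```yaml
out_dir: runs/experiment    # run directory (CLI --out overrides)
seed: 0                     # master seed for folds and per-task sub-seeds

synthetic:                  # dataset generator (dlanet.SyntheticConfig)
  image_height: 96
  image_width: 96
  n_images: 20
  seed: 0
  blob_count_ranges: [[0, 0], [3, 6], [9, 15], [20, 35]]  # per category 0-3
  blob_radius_range: [1.0, 2.0]        # Gaussian sigma, pixels
  blob_contrast_range: [0.25, 0.55]    # bump amplitude, intensity fraction
  background_texture_scale: 6.0        # smoothing sigma, pixels
  category_weights: [0.80, 0.10, 0.06, 0.04]  # per-zone sampling probabilities
  bit_depth: 8                         # 8 or 16

target_height: 48           # zone resize height; width from per-zone aspect
interpolation: bilinear     # or nearest

variants: [sequential]      # attention ablation list:
                            # none | ca | sa | sequential | parallel
ratio: 16                   # channel-attention compression ratio r
backbone: tiny              # tiny | deep

train:                      # dlanet.TrainConfig
  learning_rate: 1.0e-3
  batch_size: 4
  max_epochs: 10
  lr_reduce_factor: 0.2     # reduce-on-plateau factor
  lr_patience: 10           # epochs without val-loss improvement before reduce
  early_stop_patience: 10
  n_folds: 2                # stratified image-level folds
  seed: 0
  num_classes: 4
  augment: false
  class_weighted_loss: false
```

Outputs in the run directory: `data/` (images, masks, `manifest.csv`),
`resize_policy.fold0.yaml`, `predictions/<variant>/<ZONE>.csv`,
`report.json` (per-variant zone-level, image-level and binary-detection
summaries as fold mean ± sd%), `run.log`, `config.lock.yaml`.

The standalone subcommands `dla synth|zones|preprocess|train|evaluate`
accept the corresponding fragments; `dla synth --config` takes the
`synthetic:` block as a top-level document, `dla train --config` the
`train:` block.
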