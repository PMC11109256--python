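"""Train one zone classifier on synthetic crops and measure its accuracy.

Generates a 120-image dataset with balanced per-zone categories, extracts
and resizes the right-upper-zone crops, trains the tiny backbone with the
sequential dual-attention refinement, and reports validation accuracy
against the 0.25 chance floor of the four-category task.
"""

import tempfile

import numpy as np

from dlanet.classifier import TrainConfig, ZoneSamples, train_zone_model
from dlanet.preprocess import compute_zone_aspects, resize_zone
from dlanet.synthetic import SyntheticConfig, generate_dataset, load_image
from dlanet.zones import ZONE_NAMES, extract_zones

ZONE = "RUZ"

config = SyntheticConfig(n_images=120, seed=0)
out_dir = tempfile.mkdtemp(prefix="dla_train_")
manifest = generate_dataset(config, out_dir)

crops = []
for _, row in manifest.iterrows():
    image = load_image(out_dir, row["image_path"])
    mask = load_image(out_dir, row["mask_path"]) > 0.5
    crops.append(extract_zones(image, mask)[ZONE].pixels)

# fixed image-level 75/25 split (fold 0 = validation)
rng = np.random.default_rng(2024)
folds = np.ones(len(manifest), dtype=int)
folds[rng.permutation(len(manifest))[: len(manifest) // 4]] = 0

shapes = {z: [(1, 1)] for z in ZONE_NAMES}
shapes[ZONE] = [c.shape for c, keep in zip(crops, folds != 0) if keep]
policy = compute_zone_aspects(shapes, target_height=48)
print(f"{ZONE} resize policy: height 48, aspect 1:{policy.aspect_by_zone[ZONE]:.2f} "
      f"-> {policy.output_shape(ZONE)[1]} px wide")

samples = ZoneSamples(
    zone_name=ZONE,
    images=np.stack([resize_zone(c, ZONE, policy) for c in crops]),
    labels=manifest[ZONE].to_numpy(dtype=int),
    image_ids=manifest["image_id"].to_numpy(),
)
train_config = TrainConfig(learning_rate=1e-3, batch_size=4, max_epochs=40,
                           lr_patience=10, early_stop_patience=10, seed=0)
model, history = train_zone_model(samples, folds, 0, train_config, variant="sequential")

best = history.loc[history["val_loss"].idxmin()]
print(f"trained {len(history)} epochs; best epoch {int(best['epoch'])}: "
      f"val loss {best['val_loss']:.3f}, val accuracy {best['val_acc']:.2f}")
print("chance accuracy on the 4-category task is 0.25; the planted profusion "
      "signal is learnable far above it.")
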