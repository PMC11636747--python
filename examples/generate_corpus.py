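"""Generate and augment a synthetic fundus-like corpus.

Writes a small two-class corpus (smooth low-contrast lesions vs irregular
high-contrast lesions with satellites) as PNGs, then applies the
augmentation suite (rotation, shift, shear, zoom, flips, brightness) to one
image and reports the sampled transform parameters.
"""

import numpy as np

from csacfgd import AugmentConfig, GeneratorConfig, generate_dataset, write_dataset
from csacfgd.synth import sample_augment_params, apply_augment

samples = generate_dataset(GeneratorConfig(n_per_class=5, image_size=96, seed=0))
outdir = write_dataset(samples, "scratch_corpus")
print(f"wrote {len(samples)} images to {outdir}/ (benign/, malignant/, manifest.csv)")

rng = np.random.default_rng(1)
params = sample_augment_params(AugmentConfig(), rng)
augmented = apply_augment(samples[0].image, params)
print("sampled augmentation:", {k: round(v, 3) if isinstance(v, float) else v
                                for k, v in params.items()})
print(f"augmented image shape {augmented.shape}, dtype {augmented.dtype} "
      "(same as input; values clipped to the valid range)")
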