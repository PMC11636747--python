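"""Train the classifier head on a small synthetic fundus corpus.

Generates 20 images per class, extracts frozen stand-in features, and trains
the two-layer head with the fractional cuckoo hybrid for a short budget.
The printed history shows the batch-selected incumbent improving the
full-corpus training loss and accuracy.
"""

from csacfgd import FractionalConfig, GeneratorConfig, generate_dataset
from csacfgd.harness import run_training
from csacfgd.head import StandInExtractor, TrainConfig, extract_features

samples = generate_dataset(GeneratorConfig(n_per_class=20, seed=7))
X, y = extract_features(samples, StandInExtractor(seed=0))

train_cfg = TrainConfig(epochs=2, iterations_per_epoch=10, batch_size=32)
acc, history = run_training(
    X, y, "csa-cfgd", seed=1, train_cfg=train_cfg,
    fcfg=FractionalConfig(alpha=0.7, gamma=0.0),
)

print(history.to_string(index=False))
print(f"\nfinal training accuracy: {acc:.3f} on {len(samples)} images")
print("(accuracy is on the training corpus; this is a smoke-scale budget)")
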