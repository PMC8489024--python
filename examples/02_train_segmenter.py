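"""Train the mini-UNet on synthetic eyes (scaled-down demo).

Generates a mixed dataset, splits it 70/20/10, trains with the summed
binary-cross-entropy loss and AdaBelief, and reports the held-out mean
Dice of the best validation snapshot.  A few epochs on a few hundred
images take minutes on one CPU; the full recipe (750 epochs on the
annotated deposit) uses the same code with a different TrainConfig.
"""

import numpy as np

from pupilkit.model import build_segmenter, count_parameters
from pupilkit.synth import make_training_set
from pupilkit.training import TrainConfig, eval_crop, evaluate_dice, split_dataset, train

frames = make_training_set(200, seed=0)
train_set, val_set, test_set = split_dataset(frames, seed=0)
print(f"dataset: {len(train_set)}/{len(val_set)}/{len(test_set)} train/val/test")

model = build_segmenter(seed=0)
print(f"mini-UNet: {count_parameters(model)} parameters "
      f"({round(count_parameters(model) / 1e6, 2)} M)")

config = TrainConfig(epochs=4, seed=0)  # full recipe: epochs=750
best, history = train(model, train_set, val_set, config)
for row in history:
    print(f"  epoch {row['epoch']}: loss {row['train_loss']:.4f}, "
          f"val dice {row['val_dice']:.3f}")

test_dice = evaluate_dice(best, [eval_crop(f) for f in test_set])
print(f"held-out mean Dice: {test_dice:.3f}")
best.save("segmenter.npz")
print("saved checkpoint to segmenter.npz")
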