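# pawmoco

Self-supervised representation learning for animal-emotion images with
**momentum contrast**, evaluated by a **temperature-weighted KNN monitor**,
alongside a **SimCLR variant** and a **supervised ResNet benchmark**.

## The problem

Labeled corpora of animal affective behavior (e.g. dog photographs sorted
into Panksepp's seven primal emotion systems — Exploring, Sadness, Playing,
Rage, Fear, Affectionate, Lust) are small, expensive to curate and often
cannot be redistributed. Contrastive self-supervision sidesteps the label
bottleneck: an encoder is trained so that two random augmentations of the
*same* image map to nearby points on the unit sphere while other images are
pushed away, and the labels are touched only by a cheap non-parametric
monitor that measures how class-separated the learned embedding is.

`pawmoco` is aimed at researchers who want to run this pipeline end to end
on class-per-folder image trees — including a fully synthetic stand-in
dataset when the real images cannot be shared — on a single CPU, with every
stage deterministic under a seed.

## The method

Two encoders of identical architecture (CIFAR-recipe ResNet18/34: 3×3
stride-1 stem, no stem pooling, every batch norm replaced by **split batch
norm** with 8 groups, final 128-d L2-normalized features) process the two
augmented views of each image. The query encoder is trained by SGD with
cosine-annealed learning rate; the key encoder is an exponential moving
average θ_k ← m·θ_k + (1−m)·θ_q (m = 0.99). Keys from past batches fill a
FIFO queue of K negatives, and each example is scored by the
temperature-scaled (1+K)-way softmax cross-entropy

```
L_q = −ln [ exp(q·k⁺/τ) / ( exp(q·k⁺/τ) + Σ_i exp(q·k_i/τ) ) ],   τ = 0.1
```

with the positive key k⁺ as the target. Representation quality is tracked
each epoch by a KNN classifier over the train-split embedding bank: the
K = 200 most cosine-similar neighbors vote with weights exp(sim/0.1) on
their one-hot labels. The SimCLR variant trains a single encoder +
projection head with the in-batch NT-Xent loss (τ = 0.5) under LARS with a
linear-warmup + cosine schedule; the supervised baseline fine-tunes a
ResNet classifier head with Adam and cross-entropy.

All tensor computation is a compact numpy engine inside the package
(`pawmoco.nn`): im2col convolutions, split batch normalization, manual
reverse-mode gradients, SGD/Adam/LARS.

## Worked example

```python
from pawmoco import (SyntheticConfig, generate_synthetic_emotion_dataset,
                     EncoderConfig, MoCoTrainConfig, train_moco, chance_accuracy)

ds = generate_synthetic_emotion_dataset(
    SyntheticConfig(n_classes=7, n_per_class=60, image_size=32,
                    signal_strength=0.9, nuisance_strength=0.3, seed=1))
enc_cfg = EncoderConfig(arch="resnet18", width=16, num_bn_splits=8)
cfg = MoCoTrainConfig(batch_size=64, epochs=40, queue_size=256,
                      knn_k=200, image_resolution=32, seed=0)
encoder, history = train_moco(ds, enc_cfg, cfg)
print(f"chance:    {chance_accuracy(7):.2f}%")
print(f"epoch 1:   loss {history.train_loss.iloc[0]:.3f}, "
      f"KNN acc {history.knn_accuracy_pct.iloc[0]:.1f}%")
print(f"epoch 40:  loss {history.train_loss.iloc[-1]:.3f}, "
      f"KNN acc {history.knn_accuracy_pct.iloc[-1]:.1f}%")
```

prints (seeds as above, single CPU, ≈5 minutes):

```
chance:    14.29%
epoch 1:   loss 5.438, KNN acc 46.4%
epoch 40:  loss 4.531, KNN acc 100.0%
```

Chance for 7 balanced classes is 100/7 ≈ 14.29%; after 40 epochs the
unsupervised embedding classifies the held-out split perfectly through the
KNN monitor, while the contrastive loss has fallen from 5.44 to 4.53.
An untrained encoder of the same architecture scores ≈70% on this dataset
(color statistics leak through random convolutions), so the lift
attributable to training is the gap from 70% to 100%.

The same pipeline is available from the shell:

```bash
pawmoco generate-data --classes 7 --per-class 300 --size 96 --seed 42 --out data/
pawmoco train-moco --data data/ --arch resnet18 --resolution 96 --batch 128 \
        --lr 0.3 --momentum 0.99 --temp 0.1 --epochs 200 --knn-k 200 --out runs/
pawmoco evaluate --checkpoint runs/moco/moco_encoder.npz --data data/ --knn-k 200
pawmoco train-supervised --data data/ --arch resnet50 --epochs 20 --batch 32
```

sklearn-style estimators (`MoCoEmbedding`, `SimCLREmbedding`,
`WeightedKNNClassifier`, `SupervisedImageClassifier`) expose the same
machinery with `fit`/`transform`/`predict` for composition with sklearn
pipelines and model selection.

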