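# mfscnet

Classification of H&E-stained breast histopathology patches with a densely
connected convolutional network whose channels are re-weighted by
squeeze-and-excitation (SE) attention, plus the full experimental protocol
around it: dataset manifests for BreakHis-style directory trees, sparse-NMF
stain normalization, exact-pixel augmentation, and a confusion-matrix +
rank-AUC evaluation suite. A seeded synthetic H&E generator makes every
stage testable without downloading any external data.

The package is aimed at computational-pathology practitioners who want a
reproducible, CPU-friendly reference implementation of this family of
attention-augmented dense networks — for method study, ablation, and
small-scale experiments — rather than a production training system.

## The model

The backbone is the standard 121-layer dense network (growth rate k = 32,
blocks of 6/12/24/16 layers, compression 0.5). Each dense layer computes

    x_l = H_l([x_0, x_1, …, x_{l−1}])

on the channel concatenation of all previous feature maps, with
H = BN → ReLU → 1×1 conv(4k) → BN → ReLU → 3×3 conv(k). An SE block squeezes
each C-channel feature map to per-channel statistics — here the *optimized*
squeeze [global mean, max of the 2×2-average-pooled map, spatial variance],
a 3C descriptor — and excites gates

    s = σ(W₂ · ReLU(W₁ · z)),   W₁: 3C → C/r,  W₂: C/r → C

that rescale channels multiplicatively. Three variants differ only in where
the SE blocks sit: **C** after each dense block, **B** after each
transition layer, **A** at all seven positions. Stain normalization works
in optical density, OD = −log₁₀((I+1)/256), where Beer–Lambert makes OD
linear in stain concentration: OD ≈ W·c with W the 3×2 H&E stain matrix,
estimated by sparse non-negative matrix factorization. The AUC is the
Mann–Whitney pair statistic with half-credit ties.

## Worked example

Train a reduced variant A on synthetic two-class patches and evaluate on a
held-out set:

```python
from mfscnet import SynthParams, generate_arrays, MFSCNetClassifier, evaluate_predictions

params = SynthParams(image_size=64, n_classes=2, seed=7)
X_train, y_train = generate_arrays(params, per_class=50, seed=7)
X_test, y_test = generate_arrays(params, per_class=20, seed=8)

clf = MFSCNetClassifier(
    variant="A", growth_rate=8, block_config=(2, 2, 2, 2), se_reduction=8,
    image_size=64, learning_rate=1e-3, batch_size=32, epochs=20, seed=0,
)
clf.fit(X_train, y_train)
report = evaluate_predictions(
    y_test, clf.predict(X_test), clf.predict_proba(X_test), classes=[0, 1]
)
```

This prints (about one minute on one CPU core):

```
final training accuracy: 1.000
test accuracy:  0.900
test precision: 1.000
test recall:    0.800
test F1:        0.889
test AUC:       0.943
```

The two synthetic classes differ in nucleus density and size; the network
memorizes the training set and transfers imperfectly to new draws — the
AUC of 0.943 says a random "malignant-like" patch outscores a random
"benign-like" one 94% of the time. `MFSCNetClassifier` is a scikit-learn
estimator (`get_params`/`set_params`/`clone` work as usual), and
`StainNormalizer` is a fit/transform transformer over RGB images.

Parameter accounting of the full-size variants:

```console
$ mfscnet params --variant baseline --classes 2
baseline (2 classes): 6955906 parameters
$ mfscnet params --variant A --classes 2
A (2 classes): 7652074 parameters
$ mfscnet params --variant B --classes 2
B (2 classes): 7042874 parameters
$ mfscnet params --variant C --classes 2
C (2 classes): 7565106 parameters
```

The SE overheads are exactly additive (A − baseline = (B − baseline) +
(C − baseline) = 86 968 + 609 200 = 696 168) and independent of the class
count — these identities hold structurally for every configuration.

Other CLI entry points: `mfscnet synth` (generate a synthetic dataset
tree), `scan` (directory tree → manifest CSV), `split` (stratified 7:1:2),
`normalize` (stain-normalize a directory to a target image), `augment`
(expand the train split), and `run` (full experiment from a YAML config).

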