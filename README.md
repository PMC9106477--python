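# fdcnet

Detection and three-class classification of tumor-like objects in 2D
grayscale images and 3D volumes, built around four stages:

1. **Preprocessing** — resize, histogram equalization, median and
   Gaussian high-pass filtering, and landmark-based de-rotation
   (scale factor `BASE = √(((x₅−x₁₀)/2)² + ((y₅−y₁₀)/2)²)`, angle
   `θ = arctan(Δy/Δx)`).
2. **Morphological segmentation** — set-theoretic erosion
   `A ⊖ B = {z | B_z ⊆ A}`, dilation `A ⊕ B = {z | B̂_z ∩ A ≠ ∅}`, and
   boundary `β(A) = A − (A ⊖ B)`, with a robust spike threshold
   `3.5 · median(|x|)/0.6745` (the MAD noise estimate) seeding the
   mask from the gradient-magnitude edge map.
3. **Eigenimage features** — the snapshot method: eigendecompose the
   small `C = AᵀA` of the centered image matrix, lift via `U = AV`,
   project `y = W(x − ψ)`, and match by nearest Euclidean distance
   against a threshold τ.
4. **FDCNet classifier** — a dilated (atrous) convolution layer
   (20 channels, 3×3, rate 3), a fuzzy layer of 10 Gaussian membership
   units `φᵢ(v) = exp(−‖v−cᵢ‖²/2σᵢ²)` mixed at rate 7 and fused as
   `x = tanh(w_d·y_d + w_f·y_f + b)`, max + stochastic pooling over
   rate-11 dilated windows, and a softmax head over the classes
   *benign / malignant / suspicious*, trained by plain gradient
   descent on cross-entropy.

The network is implemented from scratch in numpy with analytic
gradients.  A deterministic synthetic phantom generator (controllable
tumor geometry, contrast, texture, and noise, with ground-truth masks)
makes every stage testable without any external dataset.  The package
targets researchers in biological image analysis who want a small,
fully inspectable reference implementation of this hybrid
fuzzy–convolutional approach.

See `docs/methods.md` for the models, parameter defaults, and design
rationale.

## Worked example

```python
import numpy as np
from fdcnet import (PhantomSpec, generate_phantom, segment_fractal,
                    generate_dataset, EigenFeatureExtractor,
                    FDCNetClassifier, TrainConfig, train,
                    multiclass_accuracy)

# segment one clean phantom against its ground-truth mask
s = generate_phantom(PhantomSpec(class_label="benign", tumor_radius=12.0,
                                 contrast=150.0, noise_gaussian_sigma=0.0,
                                 salt_pepper_rate=0.0, seed=7))
res = segment_fractal(s.image)
iou = (res.mask & s.mask).sum() / (res.mask | s.mask).sum()
print(f"segmentation threshold: {res.threshold_used:.2f} gray/px")
print(f"mask IoU vs ground truth: {iou:.3f}")

# train the classifier on 150 labeled phantoms (70/30 split)
ds = generate_dataset(150, seed=17)
X_img = np.stack([p.image.data.ravel() for p in ds])
y = np.array([p.label for p in ds])
feats = EigenFeatureExtractor(n_components=16).fit_transform(X_img)
X = np.concatenate([X_img, feats], axis=1)
clf = FDCNetClassifier(image_shape=(64, 64), random_state=42)
clf, info = train(clf, X, y, TrainConfig(seed=42, epochs=40))
te = info["test_idx"]
print(f"epochs run: {len(info['history'])}, "
      f"final training loss {info['history'][-1]:.3f}")
print(f"held-out accuracy: {multiclass_accuracy(y[te], clf.predict(X[te])):.1f}%")
```

Output:

```
segmentation threshold: 2.47 gray/px
mask IoU vs ground truth: 0.933
epochs run: 40, final training loss 0.119
held-out accuracy: 91.1%
```

The threshold (2.47 gray levels per pixel) is the MAD-based spike
level above which gradient pixels seed the mask; 0.933 IoU means the
recovered region overlaps the true tumor almost completely.  On the
full default benchmark (300 phantoms) the held-out accuracy rises to
the mid-90s.  The classifier follows the scikit-learn estimator API
(`fit` / `predict` / `predict_proba`, `get_params`), so it composes
with sklearn model selection; `EigenFeatureExtractor` is likewise a
`TransformerMixin`.

## Command line

```bash
fdcnet synth --n 100 --out data --seed 1        # phantoms + labels.csv
fdcnet run   --config cfg.yaml --seed 1 --out results
fdcnet train --data data --out model --seed 42
fdcnet predict --model model --image data/phantom_0000.png
fdcnet search --seed 0                          # pooling-layer search
fdcnet eval  --truth truth.csv --pred pred.csv
```

Exit codes: 0 success, 2 configuration error, 3 data error, 4 stage
failure.  `fdcnet run` writes per-image masks, an eigen-model archive,
a metrics JSON, and a manifest whose content hash is identical for
identical config + seed.

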