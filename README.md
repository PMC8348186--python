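# brulat — latent bruise detection in apples from SWIR hyperspectral images

Bruise damage is the most common defect in apples, and the hardest bruises
to manage are *latent* ones: subdermal damage from low impact energies
(0.013–0.2 J, far below what most detection studies use) that is invisible
to the eye and to RGB cameras for hours or days, yet already spectrally
distinct in the short-wave infrared (930–2500 nm). `brulat` is an
end-to-end, fully offline-testable pipeline for this problem, aimed at
postharvest-technology and spectral-imaging researchers:

* a **synthetic-data generator** emulating a controlled bruising
  experiment — six severity levels from calibrated ball drops, five scan
  times (1–72 h), 288-band SWIR hypercubes with ground-truth masks — so
  every downstream stage is testable without instrument data;
* **hypercube handling** — ENVI I/O, exact unfold/fold between the 3-D
  cube and the pixels × bands matrix, automated PCA + Otsu background
  removal;
* **hyperspectrograms** — PCA with per-pixel Q-residual and Hotelling-T²
  diagnostics, joined with the loading vectors into a single 1-D signal
  (57.5× compression for a 404 × 384 × 288 cube at 3 components), and
  bruise visualization by PC score images;
* **classification** — ROI mean spectra fed to four learners (quadratic
  SVM, 1-NN, shrinkage LDA, and a 30-learner random-subspace discriminant
  ensemble) under three study designs: binary latent-bruise detection,
  temporal influence, and 31-class severity assignment.

## The model in brief

A hypercube **H** (lines × samples × bands) is unfolded row-major into
**X** (n_pixels × b) and decomposed by mean-centred PCA,
T = (X − 1x̄ᵀ)P, keeping A = 3 components. Per pixel,
Q = ‖x − x̂‖² (residual off the model plane) and T² = Σₐ tₐ²/λₐ. The
hyperspectrogram concatenates the sorted distribution curves of each score,
Q and T² (n_pixels points each) with the loadings, giving a signal of
length A·b + (A+2)·n_pixels — both spectral and spatial information at
H/h = 57.5 compression for the instrument frame. Bruises invisible in the
mean image appear as high-contrast discs in PC2/PC3 score images.

Classification operates on ROI mean spectra labelled `L<level><hours>`
(e.g. L11, L318) or `sound`; 6 levels × 5 times + sound = 31 classes.
Models train with seeded stratified 10-fold cross-validation and are
evaluated by accuracy, Mann–Whitney AUC, and confusion matrices with
per-class TPR/FNR. See `docs/methods.md` for the full model, parameter
meanings and design rationale.

## Worked example

```python
import brulat as bl
from brulat.simulate import demo_config

config = demo_config()                       # 96 x 96 x 288 scan
cube, truth = bl.generate_hypercube(config, "L2", 1, seed=7)  # latent, 1 h

fruit = bl.remove_background(cube)           # PCA + Otsu segmentation
X = bl.unfold(cube)
model = bl.fit_pca(X, 3)
h = bl.build_hyperspectrogram(model, X)

outside = truth.fruit_mask & ~truth.bruise_mask
for pc in (1, 2):
    img = bl.score_image(model, X, pc)
    c = bl.mask_contrast(img, truth.bruise_mask, outside)
    print(f"PC{pc + 1} bruise contrast: {c:.1f} pooled SD")
```

prints

```
PC2 bruise contrast: 10.5 pooled SD
PC3 bruise contrast: 4.7 pooled SD
```

i.e. a one-hour-old bruise from a 0.025 J impact — invisible in the mean
image — stands 10.5 pooled standard deviations away from the surrounding
fruit in the second principal-component image. The same run reports 100%
agreement between the automated fruit mask and the simulator's ground
truth, and a hyperspectrogram of 46 944 points summarizing the
2 654 208-value cube (56.5×).

The three classification studies run from the shell:

```bash
brulat simulate --out scans/ --levels L1,L2 --hours 1,6 --n-per-cell 2
brulat detect       --out results/ --seed 7
brulat temporal     --out results/ --seed 7
brulat quantitative --out results/ --seed 7    # + confusion heatmaps
```

On the default simulation all four classifiers detect latent bruises with
≥95% held-out accuracy (the weakest level L1 is the hardest), accuracy is
non-decreasing in bruise age, and the 31-class severity models land far
below the detection models — severity, not presence, is the hard question.

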