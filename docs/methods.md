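# Methods

`brulat` re-implements, end to end and fully testable offline, a workflow for
detecting *latent* (sub-visible) bruise damage in apples from short-wave
infrared (SWIR) hyperspectral images: a synthetic-data generator emulating a
controlled bruising experiment, PCA-based background removal,
hyperspectrogram dimensionality reduction with Q-residual and Hotelling-T²
diagnostics, bruise visualization by principal-component score images, ROI
spectra extraction, and a battery of four classifiers evaluated on three
study designs (binary detection, temporal influence, quantitative severity).

## The emulated bruising experiment

A 63.79 g steel ball dropped from heights 0.020–0.319 m delivers impact
energies E = m·g·h of 0.013–0.200 J (g = 9.81 m s⁻²; the six printed
energies reproduce exactly after rounding to 3 decimals), defining severity
levels L1–L6. Each fruit side is scanned at 1, 6, 18, 48 and 72 h after
impact on a line-scan camera covering 930–2500 nm in ≈5.45 nm steps
(288 bands); the instrument frame is 404 × 384 pixels. Two batches of six
bruises per level are scanned a level-dependent number of times
(L1–L3: 4+2, L4: 4+1, L5–L6: 3+1), giving per-level totals
36, 36, 36, 30, 24, 24 and a grand total of 186 bruise observations; 287
sound-tissue ROIs accompany them (473 rows). Because severe levels were
scanned at fewer, earliest times, the *earliest-hours* schedule is assumed
(e.g. batch 1 of L5 is scanned at 1, 6 and 18 h). Severity classes combine
level and elapsed time as `L<level><hours>` (L11 … L672); six levels × five
times + `sound` gives the 31-class quantitative problem.

## Synthetic hypercubes

`generate_hypercube` paints, per scan: a dark background (reflectance 0.02),
an elliptical fruit region carrying a seeded sound-tissue spectrum, and a
circular bruise disc carrying the bruise spectrum; i.i.d. Gaussian noise
(SD 0.01 reflectance) is added per pixel and band. Every function is a pure
function of `(config, level, hours, seed)`.

**Sound tissue** is a smooth positive reflectance curve (≈0.5–0.6 over
1000–1300 nm) with multiplicative water-absorption dips at 1450 and
1940 nm. Fruit-to-fruit variation has three seeded components, chosen to be
what a practitioner would call the standard variance decomposition of such
data:

* a lognormal overall reflectance scale (σ = 0.012) — fruit differ in
  brightness even after grey-standard calibration;
* three low-amplitude smooth spectral bumps (SD 0.003) — compositional
  differences between fruit;
* within-fruit tissue heterogeneity: three smooth spatial modes (random
  low-order polynomials over the frame, RMS 1) times seeded spectral bumps
  with peak-amplitude SD 0.007, so ROIs at different positions on the same
  fruit differ by a smooth spectral offset (~0.04 L2 norm). This component
  is independent per ROI and is what keeps nearest-neighbour classifiers
  from trivially memorizing fruit identities.

**Bruised tissue** subtracts a two-component Gaussian absorbance signature
from the sound spectrum:

    depth(λ) = a₀ · (E / 0.2 J)^0.25 · [ g_w(t)·W(λ) + s·g_b(t)·B(λ) ]

with `W` peaking at 1130 and 1285 nm (water redistribution into damaged
tissue — fast: g_w(t) = 0.8 + 0.2(1 − e^(−t/12 h))) and `B` at 1650 nm
(tissue deterioration — slow: g_b(t) = 0.25 + 0.75(1 − e^(−t/24 h))), both
inside the 952–1377 / 1550–1850 nm windows where bruised and sound spectra
diverge. Full-severity amplitude a₀ = 0.20 reflectance. The design encodes
three facts about bruise spectroscopy: the spectral effect is present
immediately (latent bruises are detectable within the first hour), it grows
with time, and it saturates with impact energy (hence the 0.25 exponent —
even a 0.013 J impact produces clear subdermal damage). Severity therefore
modulates overall depth while elapsed time mostly shifts the 1650-vs-1130 nm
balance, which makes *detection* (bruised vs sound) much easier than
*severity assignment* — the qualitative structure the study reports.
Biological response varies per bruise via lognormal jitters on the overall
amplitude (σ = 0.08) and on the deterioration component (σ = 0.08); for a
fixed seed the jitters are shared across levels, so the bruise/sound
contrast is strictly increasing L1→L6 and non-decreasing in time.

Defaults are desk-scale — 64 × 64 frames, fruit semi-axes (28, 26) px,
bruise radius 6 px — so a full 360-scan dataset simulates in seconds;
`demo_config()` (96 × 96, radius 10) serves visualization and
`full_frame_config()` the full 404 × 384 frame. All size formulas take
dimensions as arguments, so instrument-frame numbers (e.g. the compression
ratio) are reproducible without instrument-frame memory.

What the generator does **not** emulate: radiometric instrument effects
(integration time, frame rate, grey-standard calibration), specular
highlights and fruit curvature shading, bruise shape irregularity, and any
chemistry beyond the three-peak signature. Passing tests therefore
demonstrate that the pipeline recovers structure *of this kind*; they are
not evidence about any particular real dataset.

## Hypercube handling

Cubes are `(line y, sample x, band b)` arrays, 0-based, with a strictly
increasing wavelength grid. Unfolding flattens the spatial axes row-major
(`p = y·n_samples + x`) into an `n_pixels × bands` matrix and is exactly
invertible. ENVI I/O writes BIL-interleaved float32 with wavelengths in the
header and reads BIL/BIP/BSQ with any supported dtype; dimension or
wavelength inconsistencies raise a `FormatError` naming the offending field.

**Background removal** replaces the original interactive contour-plot step
with an automated rule: PCA on the unfolded cube, Otsu threshold on the PC1
scores, keep the side with the higher mean broadband reflectance (PCA sign
is arbitrary), retain the largest connected component, fill holes. A
separation test (Otsu between-class distance ≥ 4 pooled within-class SDs)
rejects constant or noise-only cubes — a pure-noise Otsu split separates the
halves by only ≈2.7 pooled SDs. On simulated scans at default noise the
recovered mask agrees with the ground-truth fruit mask to ≥99%.

## Hyperspectrograms

PCA is computed by thin SVD on the mean-centred pixel matrix (no variance
scaling — standard for reflectance data); eigenvalue = singular value² /
(n − 1); each component's sign is fixed so its largest-magnitude loading
element is positive, making the decomposition deterministic. Per pixel,
Q = ‖x − x̂‖² is the squared residual off the model plane and
T² = Σₐ tₐ²/λₐ the within-model Mahalanobis distance.

A hyperspectrogram joins, in sequence, the distribution curves of the
scores (one per component), Q, and T², followed by the loading vectors.
Distribution curves are realised as **sorted per-pixel value curves**
(empirical quantile functions): the published size arithmetic
h = (3 × 288) + (404 × 384 × 5) forces each of the five curves to have
exactly n_pixels points, which a fixed-bin histogram cannot satisfy; a
100-bin histogram variant remains available (`distribution="histogram"`)
for compatibility with the wider hyperspectrogram literature. The
compression ratio (lines·samples·bands) / (A·bands + lines·samples·(A+2))
is 57.5 for a 404 × 384 × 288 cube with A = 3.

Score images fold one component's scores back to the spatial frame.
Visibility of a bruise in a component is quantified as
|mean(scores inside bruise) − mean(outside)| / pooled SD; on a simulated
latent L2 scan at 1 h, PC1 captures the background/fruit contrast and the
bruise appears in PC2 (or PC3) at ≥2 pooled SDs (typically 10–25), while a
sound scan shows <0.5 over a random disc.

## ROI dataset

Each observation is the per-band mean spectrum over a disc ROI: the bruise
disc for bruised rows, and same-radius discs of sound tissue placed
uniformly inside the fruit at ≥2 radii from any bruise pixel for sound rows
(ROI size is not standardized in practice; the radius is a config
parameter). The 287 sound ROIs are distributed round-robin over the scans
with the remainder to the earliest scans. Tables serialize to CSV with one
wavelength column per band plus label columns.

## Classifiers

* **QSVM** — SVC with the inhomogeneous quadratic kernel and one-vs-one
  multiclass, C = 1, features standardized. The inner product is
  kernel-scaled (`gamma="scale"`, i.e. ((x·z)/(p·var) + 1)²), matching the
  kernel-scale normalisation of common quadratic-SVM presets; without it the
  kernel is so ill-conditioned on hundreds of bands that C = 1 underfits
  even widely separated classes.
* **FKNN** — "fine" kNN: k = 1, Euclidean, equal weights.
* **LDA** — pooled within-class covariance discriminant. With p = 288 bands
  and a few hundred rows the small sample-covariance eigenvalues are
  severely underestimated and a naive inverse is dominated by noise
  directions, so the covariance is shrunk toward scaled identity with the
  Ledoit–Wolf intensity estimated from the class-centred residuals; a
  trace-scaled ridge (ε = 1e-6) remains only as a numerical floor,
  escalated solely if the Cholesky factorization fails.
* **ESD** — ensemble subspace discriminant: 30 of the above discriminants,
  each on a 128-feature subspace drawn uniformly without replacement,
  combined by majority vote; ties break toward the larger training prior,
  then lexicographically. With one learner on the full feature set it is
  exactly the plain discriminant.

Training uses seeded stratified k-fold cross-validation; the advertised 10
folds are clamped to the smallest class size (stratified folds are
otherwise undefined for the 6–12-row severity classes), and CV accuracy is
the pooled out-of-fold correct fraction. The returned model is refit on all
training rows, so the clamp never affects test accuracy. Binary AUC is the
Mann–Whitney statistic of the positive-class score; multiclass AUC the
unweighted mean of one-vs-rest AUCs over classes present in the test set.
Confusion matrices have true classes as rows; per-class TPR/FNR are the
diagonal fraction and its complement. Prediction speed (observations/s,
median of ≥3 timed repetitions) is reported and normalized to the fastest
entry, but never asserted in tests — it is hardware-dependent.

## Experiments

All splits are pure functions of (manifest, seed); holdouts are stratified
halves per class cell. The experiment dataset uses the complete 6 × 5 grid
(12 bruises per cell, 360 bruised + 287 sound rows) so the 31-class problem
is realizable; the truncated bookkeeping design remains available for
bookkeeping checks via `replica_manifest`.

* **detection** — binary bruised/sound. `detect-L1`/`detect-L2` hold out
  half of the target level's rows (the model must recognise held-out latent
  bruises); `overall` holds out half of the 1 h L1–L3 rows together with
  half of the sound rows.
* **temporal** — restricted to L1/L2 plus sound; for each scan time, half
  of that time's rows are held out and the model trains on all remaining
  rows across 1–72 h.
* **quantitative** — 31 classes; half of the low-severity classes at 1, 6
  and 18 h are held out and evaluated per time block and globally. An
  optional grouping map (which must cover every observed class) merges
  classes before training, e.g. into latent/visible/severe.

The five-seed battery (`run_battery`) reruns all three studies on replicate
simulations and averages test accuracies. At the default study conditions
it shows: ≥95% detection accuracy for all four families, detect-L1 ≤
detect-L2, temporal accuracy non-decreasing from 1 h to 48 h, and detection
far above 31-class severity accuracy for every family.

## Known limitations

* On this synthetic data 1-NN slightly *outperforms* the subspace ensemble
  on the 31-class severity task (five-seed means ≈31% vs ≈27%), the reverse
  of the ordering typically seen on real spectra. The tested blocks are
  exactly the classes whose training halves were removed, which biases
  empirical priors against them and leaves the prior-free 1-NN at an
  advantage; real per-observation noise is also larger and less matchable
  than the synthetic heterogeneity model. The corresponding ordering test
  is kept faithful and currently fails.
* The quadratic SVM collapses on the 31-class problem (a few percent test
  accuracy) while being the strongest detector — consistent with its known
  weakness on many-category problems; it is excluded from no analysis here.
* Ground-truth masks make ROI selection trivial; no bruise-localization
  step is provided, so performance numbers assume the bruised region is
  already known — as in the ROI-based design this package emulates.
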