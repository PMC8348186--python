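"""PCA decomposition of unfolded hypercubes and 1-D hyperspectrograms.

A hyperspectrogram compresses a hypercube of ``lines x samples x bands``
values into a single 1-D signal by joining, in sequence, the distribution
curves of the per-pixel PCA scores (one curve per retained component), the
Q residuals, the Hotelling T-squared values, and the loading vectors.  With
A components and b bands the signal has length ``A*b + 5*n_pixels`` when
A = 3 (A + 2 distribution curves of n_pixels points each plus A loading
spectra), e.g. (3 x 288) + (404 x 384 x 5) for the full instrument frame —
a 57.5-fold compression.

Distribution curves are realised as sorted per-pixel value curves (empirical
quantile functions): the published size arithmetic forces each curve to have
exactly ``n_pixels`` points, which rules out a fixed-bin histogram.  A
100-bin histogram variant is available via ``distribution="histogram"`` for
compatibility with the wider hyperspectrogram literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypercube import PixelMatrix


@dataclass
class PCAModel:
    """Mean-centred PCA: ``scores = (X - mean) @ loadings.T``.

    ``loadings`` rows are orthonormal basis spectra (A x b); ``eigenvalues``
    are the score variances, non-increasing.  Component signs are fixed so
    the largest-magnitude element of each loading is positive, making the
    decomposition deterministic across runs.
    """

    mean: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self):
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("loadings rows must be orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")
        if np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be non-negative")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_bands(self) -> int:
        return self.loadings.shape[1]

    def scores(self, X: PixelMatrix) -> np.ndarray:
        self._check_bands(X)
        return (X.values - self.mean) @ self.loadings.T

    def _check_bands(self, X: PixelMatrix):
        if X.n_bands != self.n_bands:
            raise ValueError(
                f"band count mismatch: model has {self.n_bands}, matrix has "
                f"{X.n_bands}"
            )


def fit_pca(X: PixelMatrix, A: int) -> PCAModel:
    """Fit an A-component mean-centred PCA via thin SVD.

    Eigenvalue = singular_value^2 / (n_pixels - 1).  No variance scaling is
    applied (standard for reflectance chemometrics).
    """
    n, b = X.values.shape
    if not (1 <= A <= min(n, b)):
        raise ValueError(f"A must be in [1, min(n_pixels, n_bands)] = "
                         f"[1, {min(n, b)}], got {A}")
    if not np.all(np.isfinite(X.values)):
        raise ValueError("pixel matrix contains non-finite values")
    mean = X.values.mean(axis=0)
    centred = X.values - mean
    # thin SVD; only the top A right singular vectors are kept
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    loadings = vt[:A]
    eigenvalues = (s[:A] ** 2) / max(n - 1, 1)
    # sign convention: largest-magnitude loading element positive
    for i in range(A):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    return PCAModel(mean, loadings.copy(), eigenvalues)


def q_residual(model: PCAModel, X: PixelMatrix) -> np.ndarray:
    """Per-pixel squared reconstruction error off the PCA plane."""
    model._check_bands(X)
    centred = X.values - model.mean
    residual = centred - (centred @ model.loadings.T) @ model.loadings
    return np.einsum("ij,ij->i", residual, residual)


def hotelling_t2(model: PCAModel, X: PixelMatrix) -> np.ndarray:
    """Per-pixel Hotelling T²: sum over components of score² / eigenvalue."""
    model._check_bands(X)
    if np.any(model.eigenvalues <= 0):
        raise ValueError("Hotelling T² undefined: a retained eigenvalue is zero")
    t = model.scores(X)
    return np.einsum("ia,ia->i", t, t / model.eigenvalues)


@dataclass
class Hyperspectrogram:
    """1-D hypercube summary with a named segment map.

    ``segments`` is an ordered list of ``(name, start, stop)`` slices into
    ``signal``; names are ``score_pc1..score_pcA``, ``q_residual``,
    ``hotelling_t2``, ``loadings``.
    """

    signal: np.ndarray
    segments: list[tuple[str, int, int]]

    def __post_init__(self):
        total = sum(stop - start for _, start, stop in self.segments)
        if total != self.signal.size:
            raise ValueError("segment lengths must sum to the signal length")

    def segment(self, name: str) -> np.ndarray:
        for seg_name, start, stop in self.segments:
            if seg_name == name:
                return self.signal[start:stop]
        raise KeyError(name)

    def to_frame(self):
        """Single-column DataFrame plus a JSON-ready segment map."""
        import pandas as pd

        frame = pd.DataFrame({"value": self.signal})
        seg_map = [{"name": n, "start": int(a), "stop": int(b)}
                   for n, a, b in self.segments]
        return frame, seg_map


def build_hyperspectrogram(model: PCAModel, X: PixelMatrix,
                           distribution: str = "sorted",
                           n_bins: int = 100) -> Hyperspectrogram:
    """Join score/Q/T² distribution curves and the loading vectors.

    ``distribution="sorted"`` (default) uses per-pixel sorted value curves of
    length ``n_pixels`` each; ``"histogram"`` uses fixed-bin counts of length
    ``n_bins``.
    """
    if distribution not in ("sorted", "histogram"):
        raise ValueError(f"unknown distribution kind {distribution!r}")
    scores = model.scores(X)
    curves = [scores[:, a] for a in range(model.n_components)]
    curves.append(q_residual(model, X))
    curves.append(hotelling_t2(model, X))
    if distribution == "sorted":
        curves = [np.sort(c) for c in curves]
    else:
        curves = [np.histogram(c, bins=n_bins)[0].astype(float) for c in curves]

    names = [f"score_pc{a + 1}" for a in range(model.n_components)]
    names += ["q_residual", "hotelling_t2"]
    pieces = curves + [model.loadings.ravel()]
    names.append("loadings")

    segments, start = [], 0
    for name, piece in zip(names, pieces):
        segments.append((name, start, start + piece.size))
        start += piece.size
    return Hyperspectrogram(np.concatenate(pieces), segments)


def compression_ratio(lines: int, samples: int, bands: int, A: int) -> float:
    """Hypercube size over hyperspectrogram size, to 1 decimal place.

    ``(lines*samples*bands) / (A*bands + lines*samples*(A+2))`` — 57.5 for a
    404 x 384 x 288 cube with 3 components.
    """
    if min(lines, samples, bands, A) < 1:
        raise ValueError("all dimensions must be positive")
    h = A * bands + lines * samples * (A + 2)
    return round(lines * samples * bands / h, 1)


def score_image(model: PCAModel, X: PixelMatrix, component: int,
                shape: tuple[int, int] | None = None,
                rescale: bool = False) -> np.ndarray:
    """Fold the scores of one component back to the spatial frame.

    ``rescale=True`` min-max scales to [0, 1] for display export.  ``X`` must
    be a full-frame (unmasked) row-major unfolding of the given shape.
    """
    if not (0 <= component < model.n_components):
        raise ValueError(f"component {component} out of range "
                         f"[0, {model.n_components})")
    shape = shape or X.shape_origin
    lines, samples = shape
    if X.pixel_indices is not None or X.n_pixels != lines * samples:
        raise ValueError(f"shape {shape} inconsistent with {X.n_pixels} pixels")
    img = model.scores(X)[:, component].reshape(lines, samples)
    if rescale:
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return img


def mask_contrast(image: np.ndarray, inside: np.ndarray,
                  outside: np.ndarray) -> float:
    """|mean(inside) - mean(outside)| in units of the pooled within-group SD.

    The statistic behind "the bruise is visible in this component": a bruise
    disc whose mean score sits >= 2 pooled SDs away from the surrounding
    fruit is clearly contrasted.
    """
    a, b = image[inside], image[outside]
    if a.size < 2 or b.size < 2:
        raise ValueError("both regions need at least 2 pixels")
    pooled = np.sqrt((a.var(ddof=1) * (a.size - 1) + b.var(ddof=1) * (b.size - 1))
                     / (a.size + b.size - 2))
    if pooled == 0:
        return np.inf if a.mean() != b.mean() else 0.0
    return float(abs(a.mean() - b.mean()) / pooled)
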