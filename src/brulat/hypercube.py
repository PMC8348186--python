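"""Hypercube container, ENVI I/O, unfolding and PCA-based background removal.

A hypercube is a 3-D reflectance array indexed (line y, sample x, band b),
0-based, with a strictly increasing wavelength grid in nanometres.  Unfolding
flattens the two spatial axes row-major (pixel p = y * n_samples + x) into an
(n_pixels x n_bands) matrix, the working representation for all multivariate
steps; folding inverts it exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label


class FormatError(ValueError):
    """Raised when an ENVI header/binary pair is inconsistent or incomplete."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band-centre wavelengths in nanometres."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D sequence")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def __array__(self, dtype=None, copy=None):
        return np.array(self.values, dtype=dtype)


def nearest_band(grid: WavelengthGrid, target_nm: float) -> int:
    """Index of the band closest to ``target_nm`` (ties toward lower index)."""
    values = np.asarray(grid)
    return int(np.argmin(np.abs(values - float(target_nm))))


@dataclass
class Hypercube:
    """3-D reflectance image: ``data[line, sample, band]``."""

    data: np.ndarray
    wavelengths: WavelengthGrid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("hypercube data must be 3-D (lines, samples, bands)")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all hypercube dimensions must be >= 1")
        if self.data.shape[2] != len(self.wavelengths):
            raise ValueError(
                f"band axis ({self.data.shape[2]}) does not match wavelength "
                f"grid length ({len(self.wavelengths)})"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_image(self, target_nm: float) -> np.ndarray:
        """Single-wavelength image at the band nearest ``target_nm``."""
        return self.data[:, :, nearest_band(self.wavelengths, target_nm)]


@dataclass
class PixelMatrix:
    """Unfolded cube: one row per pixel, one column per band."""

    values: np.ndarray
    shape_origin: tuple[int, int]
    pixel_indices: np.ndarray | None = None  # set when mask-restricted

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("pixel matrix must be 2-D")
        lines, samples = self.shape_origin
        if self.pixel_indices is None:
            if self.values.shape[0] != lines * samples:
                raise ValueError("row count must equal lines * samples")
        elif self.values.shape[0] != len(self.pixel_indices):
            raise ValueError("row count must match pixel index list")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]


def unfold(cube: Hypercube, mask: np.ndarray | None = None) -> PixelMatrix:
    """Flatten spatial axes row-major into an (n_pixels x n_bands) matrix.

    With a boolean ``mask`` only the selected pixels are kept and their flat
    row-major indices recorded so images can be reassembled later.
    """
    lines, samples, bands = cube.shape
    flat = cube.data.reshape(lines * samples, bands)
    if mask is None:
        return PixelMatrix(flat.copy(), (lines, samples))
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (lines, samples):
        raise ValueError(
            f"mask shape {mask.shape} does not match spatial dims {(lines, samples)}"
        )
    idx = np.flatnonzero(mask.ravel())
    return PixelMatrix(flat[idx].copy(), (lines, samples), pixel_indices=idx)


def fold(matrix: PixelMatrix, wavelengths: WavelengthGrid | None = None,
         fill_value: float = 0.0) -> np.ndarray:
    """Reshape an unfolded matrix back to (lines, samples, bands).

    Mask-restricted matrices are padded with ``fill_value`` at unselected
    pixels.  Returns a plain array; wrap in :class:`Hypercube` with the grid
    if needed.
    """
    lines, samples = matrix.shape_origin
    bands = matrix.n_bands
    if matrix.pixel_indices is None:
        return matrix.values.reshape(lines, samples, bands).copy()
    out = np.full((lines * samples, bands), fill_value, dtype=matrix.values.dtype)
    out[matrix.pixel_indices] = matrix.values
    return out.reshape(lines, samples, bands)


# --------------------------------------------------------------------------
# ENVI I/O
# --------------------------------------------------------------------------

_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _header_path(path: Path) -> Path:
    return path if path.suffix == ".hdr" else path.with_name(path.name + ".hdr")


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic line)")
    # collapse brace-delimited multi-line values, then parse key = value lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(path: str | Path) -> Hypercube:
    """Read an ENVI header/binary pair (BIL, BIP or BSQ interleave)."""
    path = Path(path)
    hdr_path = _header_path(path)
    if not hdr_path.exists():
        raise FormatError(f"header file not found: {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())

    def _require_int(name: str) -> int:
        if name not in fields:
            raise FormatError(f"ENVI header missing required field '{name}'")
        return int(fields[name])

    lines = _require_int("lines")
    samples = _require_int("samples")
    bands = _require_int("bands")
    dtype_code = _require_int("data type")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported interleave '{interleave}'")

    if "wavelength" not in fields:
        raise FormatError("ENVI header missing required field 'wavelength'")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array(
        [float(t) for t in wl_text.replace(",", " ").split()], dtype=float
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"wavelength list length ({wavelengths.size}) does not match "
            f"'bands' ({bands})"
        )

    data_path = hdr_path.with_name(hdr_path.name[:-len(".hdr")])
    if not data_path.exists():
        raise FormatError(f"binary data file not found: {data_path}")
    offset = int(fields.get("header offset", "0"))
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    if raw.size != lines * samples * bands:
        raise FormatError(
            f"binary size ({raw.size} values) does not match header dimensions "
            f"lines*samples*bands = {lines * samples * bands}"
        )
    if interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)

    metadata = {
        k: v for k, v in fields.items()
        if k not in ("lines", "samples", "bands", "data type", "byte order",
                     "interleave", "wavelength", "header offset")
    }
    return Hypercube(np.ascontiguousarray(data), WavelengthGrid(wavelengths), metadata)


def write_envi(cube: Hypercube, path: str | Path, interleave: str = "bil",
               dtype=np.float32) -> Path:
    """Write ``cube`` as an ENVI pair ``path`` + ``path.hdr``.

    Default dialect: BIL interleave, float32, little-endian, wavelengths in
    the header.  Returns the binary data path.
    """
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave '{interleave}'")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported dtype {dtype}")
    data = cube.data.astype(dtype)
    if interleave == "bil":
        ordered = data.transpose(0, 2, 1)
    elif interleave == "bsq":
        ordered = data.transpose(2, 0, 1)
    else:
        ordered = data
    path.parent.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(ordered).tofile(path)

    wl = ", ".join(f"{w:.6f}" for w in np.asarray(cube.wavelengths))
    lines, samples, bands = cube.shape
    header = (
        "ENVI\n"
        "description = {brulat hypercube}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    _header_path(path).write_text(header)
    return path


# --------------------------------------------------------------------------
# Background removal
# --------------------------------------------------------------------------

def remove_background(cube: Hypercube, n_pcs: int = 2) -> np.ndarray:
    """Segment fruit from background; returns a boolean fruit mask.

    Automated stand-in for interactive PCA contour-plot editing: PCA on the
    unfolded cube, Otsu threshold on PC1 scores, keep the side with the higher
    mean broadband reflectance, retain the largest connected component and
    fill holes.  Raises ``ValueError`` when the cube has no separable
    foreground (constant or noise-only image).
    """
    from .hyperspectrogram import fit_pca  # local import avoids cycle

    matrix = unfold(cube)
    total_var = float(np.var(matrix.values, axis=0, ddof=1).sum())
    if total_var <= 0 or not np.isfinite(total_var):
        raise ValueError("no separable background: cube is constant")
    model = fit_pca(matrix, min(n_pcs, min(matrix.n_pixels - 1, matrix.n_bands)))
    pc1 = (matrix.values - model.mean) @ model.loadings[0]

    threshold = threshold_otsu(pc1)
    side = pc1 > threshold
    if side.all() or not side.any():
        raise ValueError("no separable background: Otsu split is degenerate")
    # Demand genuine bimodality; pure noise splits at ~1.5 within-class SD.
    lo, hi = pc1[~side], pc1[side]
    pooled_sd = np.sqrt((lo.var(ddof=1) * (lo.size - 1) + hi.var(ddof=1) * (hi.size - 1))
                        / (lo.size + hi.size - 2))
    if pooled_sd == 0 or (hi.mean() - lo.mean()) < 4.0 * pooled_sd:
        raise ValueError("no separable background: PC1 scores are unimodal")

    broadband = matrix.values.mean(axis=1)
    fruit_flat = side if broadband[side].mean() >= broadband[~side].mean() else ~side
    mask = fruit_flat.reshape(cube.n_lines, cube.n_samples)

    labels = cc_label(mask, connectivity=2)
    if labels.max() > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a boolean mask stored as an 8-bit PNG."""
    import imageio.v3 as iio

    return np.asarray(iio.imread(path)) > 0


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as an 8-bit PNG (255 = True)."""
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path
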