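"""ROI mean-spectrum extraction and labelled spectra tables.

One classification observation is the per-band mean spectrum over a region
of interest (ROI): either a bruise disc or a same-sized disc of sound tissue
sampled away from any bruise.  Class labels combine bruise level and hours
since impact as "Lxyz" (level x, recorded after y or yz hours), e.g. L11,
L318; sound tissue is labelled "sound".  Six levels x five scan times plus
sound give the 31-class severity problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .hypercube import Hypercube, WavelengthGrid, read_envi, read_mask
from .simulate import (REPLICA_SCHEDULE, SCAN_HOURS, GroundTruth,
                       SimulationConfig, generate_hypercube)

#: every (level number, hours) cell of the complete scan grid
FULL_SCHEDULE = frozenset((lv, h) for lv in range(1, 7) for h in SCAN_HOURS)

#: cells actually scanned in the truncated study bookkeeping
TABLE1_SCHEDULE = frozenset(
    (int(level[1]), h)
    for batch in REPLICA_SCHEDULE.values()
    for level, hours in batch.items()
    for h in hours
)


def roi_mean_spectrum(cube: Hypercube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean over the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (cube.n_lines, cube.n_samples):
        raise ValueError(f"mask shape {mask.shape} does not match frame "
                         f"{(cube.n_lines, cube.n_samples)}")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return cube.data[mask].mean(axis=0)


def class_code(level: int, hours: int,
               schedule: frozenset = FULL_SCHEDULE) -> str:
    """Severity class label "L<level><hours>" (no separator), e.g. L318.

    Raises for combinations outside ``schedule``; the default full schedule
    admits all 6 x 5 cells, ``TABLE1_SCHEDULE`` only those actually scanned.
    """
    if (level, hours) not in FULL_SCHEDULE:
        raise ValueError(f"invalid class: level must be 1..6 and hours one of "
                         f"{SCAN_HOURS}, got ({level}, {hours})")
    if (level, hours) not in schedule:
        raise ValueError(f"combination L{level} at {hours} h is not in the "
                         f"scan schedule")
    return f"L{level}{hours}"


def parse_class_code(code: str) -> tuple[int, int]:
    """Inverse of :func:`class_code`: "L318" -> (3, 18)."""
    if len(code) < 3 or code[0] != "L" or not code[1:].isdigit():
        raise ValueError(f"malformed class code {code!r}")
    level, hours = int(code[1]), int(code[2:])
    if (level, hours) not in FULL_SCHEDULE:
        raise ValueError(f"class code {code!r} outside the level/hour grid")
    return level, hours


def all_class_codes(schedule: frozenset = FULL_SCHEDULE,
                    include_sound: bool = True) -> list[str]:
    """Severity-ordered class labels; 31 entries for the full schedule."""
    codes = [f"L{lv}{h}" for lv in range(1, 7) for h in SCAN_HOURS
             if (lv, h) in schedule]
    return (["sound"] + codes) if include_sound else codes


@dataclass
class LabeledSpectrum:
    """One classifier observation: an ROI mean spectrum plus its labels."""

    spectrum: np.ndarray
    status: str                  # "bruised" | "sound"
    level: str                   # "L1".."L6" | "none"
    hours: int
    batch: int
    class_code: str

    def __post_init__(self):
        if self.status not in ("bruised", "sound"):
            raise ValueError(f"status must be 'bruised' or 'sound', got {self.status!r}")
        if self.status == "sound" and self.level != "none":
            raise ValueError("sound spectra must have level 'none'")
        if self.status == "bruised":
            expected = class_code(int(self.level[1]), self.hours)
            if self.class_code != expected:
                raise ValueError(f"class code {self.class_code!r} inconsistent "
                                 f"with ({self.level}, {self.hours})")
        elif self.class_code != "sound":
            raise ValueError("sound spectra must have class code 'sound'")


@dataclass
class SpectraTable:
    """Rows of labelled ROI spectra sharing one wavelength grid."""

    rows: list[LabeledSpectrum]
    wavelengths: WavelengthGrid

    def __post_init__(self):
        b = len(self.wavelengths)
        for row in self.rows:
            if row.spectrum.size != b:
                raise ValueError("all rows must share the table band count")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def X(self) -> np.ndarray:
        return np.vstack([r.spectrum for r in self.rows]) if self.rows else \
            np.empty((0, len(self.wavelengths)))

    def labels(self, kind: str = "class_code") -> np.ndarray:
        """Label vector: 'class_code', 'status', 'level' or 'hours'."""
        return np.array([getattr(r, kind) for r in self.rows])

    def counts(self) -> pd.Series:
        return pd.Series(self.labels("class_code")).value_counts().sort_index()

    def to_dataframe(self) -> pd.DataFrame:
        wl_cols = [f"wl_{i + 1}" for i in range(len(self.wavelengths))]
        df = pd.DataFrame(self.X, columns=wl_cols)
        for kind in ("status", "level", "hours", "class_code", "batch"):
            df[kind] = self.labels(kind)
        return df

    def to_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path, wavelengths: WavelengthGrid) -> "SpectraTable":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c.startswith("wl_")]
        if len(wl_cols) != len(wavelengths):
            raise ValueError("CSV band count does not match wavelength grid")
        rows = [
            LabeledSpectrum(row[wl_cols].to_numpy(dtype=float), row["status"],
                            row["level"], int(row["hours"]), int(row["batch"]),
                            row["class_code"])
            for _, row in df.iterrows()
        ]
        return cls(rows, wavelengths)


def sample_sound_roi_centers(truth: GroundTruth, radius: int, n: int,
                             rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniformly sample ``n`` disc centres of sound tissue inside the fruit.

    A centre is valid when its disc lies fully inside the fruit mask and its
    distance to the nearest bruise pixel is at least two radii.
    """
    interior = ndimage.binary_erosion(truth.fruit_mask,
                                      iterations=radius + 1)
    if truth.bruise_mask.any():
        away = ndimage.distance_transform_edt(~truth.bruise_mask) >= 2 * radius
        interior &= away
    valid = np.argwhere(interior)
    if len(valid) == 0:
        raise ValueError("no room for a sound ROI in this frame")
    picks = rng.choice(len(valid), size=n, replace=len(valid) < n)
    return [tuple(valid[p]) for p in np.atleast_1d(picks)]


def disc_mask(shape: tuple[int, int], center: tuple[int, int],
              radius: int) -> np.ndarray:
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def _round_robin(total: int, n_cells: int) -> list[int]:
    base, rem = divmod(total, n_cells)
    return [base + (1 if i < rem else 0) for i in range(n_cells)]


def _disk_loader(row) -> tuple[Hypercube, GroundTruth]:
    path = Path(row.cube_path)
    if not path.exists() and not path.with_name(path.name + ".hdr").exists():
        raise FileNotFoundError(path)
    cube = read_envi(path)
    fruit = read_mask(path.with_name(path.stem + "_fruit.png"))
    bruise = read_mask(path.with_name(path.stem + "_bruise.png"))
    return cube, GroundTruth(fruit, bruise, row.level, int(row.hours))


def assemble_dataset(manifest: pd.DataFrame, sound_total: int = 287,
                     config: SimulationConfig | None = None,
                     loader=None) -> SpectraTable:
    """Build the labelled spectra table from an experiment manifest.

    One bruised row per manifest scan (the bruise-disc mean spectrum) plus
    ``sound_total`` sound rows sampled as same-radius discs of unbruised
    tissue, distributed round-robin over the scans (remainder to the earliest
    scans).  By default scans are read from ``cube_path`` (ENVI + PNG masks);
    when ``config`` is given and paths are empty, cubes are regenerated in
    memory from the manifest seeds.
    """
    config = config or SimulationConfig()
    if loader is None:
        def loader(row):
            if getattr(row, "cube_path", ""):
                return _disk_loader(row)
            return generate_hypercube(config, row.level, int(row.hours),
                                      int(row.seed))

    wavelengths = config.grid
    n = len(manifest)
    if n == 0:
        return SpectraTable([], wavelengths)

    sound_counts = _round_robin(sound_total, n)
    rows: list[LabeledSpectrum] = []
    sound_rows: list[LabeledSpectrum] = []
    missing = []
    for i, row in enumerate(manifest.itertuples(index=False)):
        try:
            cube, truth = loader(row)
        except FileNotFoundError as err:
            missing.append(str(err))
            continue
        if truth.bruise_mask.any():
            spectrum = roi_mean_spectrum(cube, truth.bruise_mask)
            level_num = int(row.level[1])
            rows.append(LabeledSpectrum(
                spectrum, "bruised", row.level, int(row.hours),
                int(row.batch), class_code(level_num, int(row.hours))))
        if sound_counts[i]:
            rng = np.random.default_rng((int(row.seed) * 31 + 17) % (2 ** 31))
            radius = config.bruise_radius_px
            for center in sample_sound_roi_centers(truth, radius,
                                                   sound_counts[i], rng):
                mask = disc_mask(truth.fruit_mask.shape, center, radius)
                mask &= truth.fruit_mask
                sound_rows.append(LabeledSpectrum(
                    roi_mean_spectrum(cube, mask), "sound", "none",
                    int(row.hours), int(row.batch), "sound"))
    if missing:
        raise FileNotFoundError("manifest references missing cubes:\n"
                                + "\n".join(missing))
    return SpectraTable(rows + sound_rows, wavelengths)
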