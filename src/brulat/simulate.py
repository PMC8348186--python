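"""Synthetic SWIR hypercube generation emulating an apple-bruising study.

The generator reproduces the structure of a controlled bruising experiment:
a steel ball (63.79 g) dropped from six calibrated heights onto Golden
Delicious apples creates six bruise-severity levels L1..L6 (impact energies
0.013-0.200 J), each fruit scanned at 1, 6, 18, 48 and 72 h after impact on a
line-scan SWIR camera (930-2500 nm in ~5.45 nm steps, 288 bands).

Spectra are modelled, not measured: sound apple tissue is a smooth
reflectance curve with water-absorption dips near 1450 and 1940 nm; a bruise
lowers reflectance (raises absorbance) in Gaussian bumps centred at 1130,
1285 and 1650 nm — inside the 952-1377 and 1550-1850 nm windows where
bruised/sound spectra diverge — with an amplitude that grows with impact
energy and with hours since impact.  Every function is a pure function of its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypercube import Hypercube, WavelengthGrid

BALL_MASS_KG = 0.06379
STANDARD_GRAVITY = 9.81  # 9.8 fails to reproduce the L6 energy after rounding
REFERENCE_ENERGY_J = 0.200  # L6: amplitude model is scaled to this impact
SCAN_HOURS = (1, 6, 18, 48, 72)
LEVEL_CODES = ("L1", "L2", "L3", "L4", "L5", "L6")

_DROP_HEIGHTS_M = (0.020, 0.040, 0.07, 0.126, 0.219, 0.319)
_TIMES_BATCH1 = (4, 4, 4, 4, 3, 3)
_TIMES_BATCH2 = (2, 2, 2, 1, 1, 1)

# Severe levels were scanned at fewer, earliest time points; batch 2 fruit
# were re-scanned least.  Hours are taken earliest-first.
REPLICA_SCHEDULE = {
    1: {code: SCAN_HOURS[:n] for code, n in zip(LEVEL_CODES, _TIMES_BATCH1)},
    2: {code: SCAN_HOURS[:n] for code, n in zip(LEVEL_CODES, _TIMES_BATCH2)},
}


def energy_from_drop(mass_kg: float, height_m: float,
                     g: float = STANDARD_GRAVITY) -> float:
    """Free-fall impact energy m*g*h in joules, rounded to 3 decimals."""
    if mass_kg <= 0:
        raise ValueError(f"mass must be positive, got {mass_kg}")
    if height_m < 0:
        raise ValueError(f"drop height must be non-negative, got {height_m}")
    return round(mass_kg * g * height_m, 3)


@dataclass(frozen=True)
class BruiseLevel:
    """One severity level of the bruising experiment."""

    code: str
    drop_height_m: float
    impact_energy_J: float
    times_scanned_batch1: int
    times_scanned_batch2: int
    bruises_per_batch: int = 6

    @property
    def total_samples(self) -> int:
        return self.bruises_per_batch * (self.times_scanned_batch1
                                         + self.times_scanned_batch2)


def severity_table() -> list[BruiseLevel]:
    """The six severity levels with energies derived from drop heights."""
    return [
        BruiseLevel(code, h, energy_from_drop(BALL_MASS_KG, h), t1, t2)
        for code, h, t1, t2 in zip(LEVEL_CODES, _DROP_HEIGHTS_M,
                                   _TIMES_BATCH1, _TIMES_BATCH2)
    ]


def grand_total(levels: list[BruiseLevel] | None = None) -> int:
    """Total bruise samples over all levels (186 for the study design)."""
    return sum(lv.total_samples for lv in levels or severity_table())


def level_by_code(code: str) -> BruiseLevel:
    for lv in severity_table():
        if lv.code == code:
            return lv
    raise ValueError(f"unknown bruise level {code!r}; expected L1..L6")


# --------------------------------------------------------------------------
# Spectral model
# --------------------------------------------------------------------------

#: fast component: water redistribution into intercellular space
WATER_PEAKS_NM = ((1130.0, 1.0, 40.0), (1285.0, 0.9, 40.0))
#: slow component: tissue deterioration / browning
DETERIORATION_PEAKS_NM = ((1650.0, 0.8, 50.0),)


def sound_spectrum(grid: WavelengthGrid | np.ndarray, seed: int,
                   variability_sd: float = 0.003,
                   scale_sd: float = 0.012) -> np.ndarray:
    """Reflectance spectrum of healthy apple tissue on ``grid``.

    Smooth positive curve in (0, 1] with multiplicative water-band dips at
    1450 and 1940 nm, plus seeded fruit-to-fruit variation: a lognormal
    overall reflectance scale (``scale_sd``, a few percent, as real fruit
    differ in brightness even after grey-standard calibration) and three
    low-amplitude smooth shape bumps (``variability_sd``).  Deterministic
    per seed.
    """
    wl = np.asarray(grid, dtype=float)
    if wl.size == 0:
        raise ValueError("wavelength grid is empty")
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    base = 0.18 + 0.42 * np.exp(-(((wl - 1150.0) / 550.0) ** 2))
    base *= 1.0 - 0.35 * np.exp(-(((wl - 1450.0) / 55.0) ** 2))
    base *= 1.0 - 0.55 * np.exp(-(((wl - 1940.0) / 90.0) ** 2))
    rng = np.random.default_rng(seed)
    base *= np.exp(rng.normal(0.0, scale_sd))
    for _ in range(3):
        centre = rng.uniform(wl[0], wl[-1])
        width = rng.uniform(30.0, 80.0)
        amp = rng.normal(0.0, variability_sd)
        base += amp * np.exp(-(((wl - centre) / width) ** 2))
    return np.clip(base, 1e-3, 1.0)


def _peak_profile(wl: np.ndarray, peaks) -> np.ndarray:
    profile = np.zeros_like(wl)
    for centre, weight, width in peaks:
        profile += weight * np.exp(-(((wl - centre) / width) ** 2))
    return profile


def bruise_spectrum(sound: np.ndarray, energy_J: float, hours: float,
                    grid: WavelengthGrid | np.ndarray,
                    amplitude: float = 0.20, energy_exponent: float = 0.25,
                    deterioration_scale: float = 1.0) -> np.ndarray:
    """Reflectance of bruised tissue given the sound spectrum.

    The bruise subtracts two Gaussian absorbance components::

        depth(lam) = amplitude * (E / 0.2 J)**energy_exponent
                     * [ g_w(t) * W(lam) + s * g_b(t) * B(lam) ]

    ``W`` peaks at 1130/1285 nm (water redistribution into damaged tissue;
    fast, g_w(t) = 0.8 + 0.2*(1 - exp(-t/12 h))) and ``B`` at 1650 nm
    (deterioration/browning; slow, g_b(t) = 0.25 + 0.75*(1 - exp(-t/24 h))),
    both inside the 952-1377 / 1550-1850 nm windows where bruised and sound
    spectra diverge.  Impact severity thus sets the overall depth —
    sublinearly in energy, since tissue damage saturates — while elapsed
    time mostly shifts the 1650-vs-1130 nm balance.  ``deterioration_scale``
    (``s``) rescales the slow component (per-fruit variability hook).
    Identity at ``energy_J == 0``; the gap grows strictly with energy and
    monotonically with hours.
    """
    if energy_J < 0:
        raise ValueError(f"impact energy must be non-negative, got {energy_J}")
    if hours < 0:
        raise ValueError(f"hours must be non-negative, got {hours}")
    sound = np.asarray(sound, dtype=float)
    wl = np.asarray(grid, dtype=float)
    if sound.shape != wl.shape:
        raise ValueError("sound spectrum and grid lengths differ")
    if energy_J == 0:
        return sound.copy()
    scale = amplitude * (energy_J / REFERENCE_ENERGY_J) ** energy_exponent
    g_w = 0.8 + 0.2 * (1.0 - np.exp(-hours / 12.0))
    g_b = 0.25 + 0.75 * (1.0 - np.exp(-hours / 24.0))
    depth = scale * (g_w * _peak_profile(wl, WATER_PEAKS_NM)
                     + deterioration_scale * g_b
                     * _peak_profile(wl, DETERIORATION_PEAKS_NM))
    return np.clip(sound - depth, 0.01, 1.0)


# --------------------------------------------------------------------------
# Cube generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, wavelength grid and noise model of one simulated scan.

    Defaults are a desk-scale frame (64 x 64); the full instrument frame
    (404 x 384) is supported by overriding ``lines``/``samples`` and scaling
    the fruit geometry.
    """

    lines: int = 64
    samples: int = 64
    band_start_nm: float = 930.0
    band_step_nm: float = 5.45
    band_count: int = 288
    fruit_axes: tuple[int, int] = (28, 26)   # ellipse semi-axes (y, x), px
    bruise_radius_px: int = 6
    noise_sd: float = 0.01
    background_reflectance: float = 0.02
    bruise_amplitude: float = 0.20
    energy_exponent: float = 0.25
    amplitude_jitter_sd: float = 0.08
    deterioration_jitter_sd: float = 0.08
    fruit_variability_sd: float = 0.003
    fruit_scale_sd: float = 0.012
    tissue_heterogeneity_sd: float = 0.007
    seed: int = 0

    def __post_init__(self):
        if self.lines < 1 or self.samples < 1:
            raise ValueError("frame dimensions must be positive")
        if self.band_count < 2:
            raise ValueError("band_count must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        ay, ax = self.fruit_axes
        if ay <= 0 or ax <= 0:
            raise ValueError("fruit ellipse semi-axes must be positive")
        if 2 * ay >= self.lines or 2 * ax >= self.samples:
            raise ValueError("fruit ellipse does not fit inside the frame")
        if self.bruise_radius_px <= 0:
            raise ValueError("bruise radius must be positive")
        if self.bruise_radius_px >= min(ay, ax):
            raise ValueError("bruise disc does not fit inside the fruit ellipse")

    @property
    def grid(self) -> WavelengthGrid:
        wl = self.band_start_nm + self.band_step_nm * np.arange(self.band_count)
        return WavelengthGrid(wl)


def demo_config(**overrides) -> SimulationConfig:
    """Larger frame used for visualization examples (96 x 96, radius 10)."""
    params = dict(lines=96, samples=96, fruit_axes=(40, 36), bruise_radius_px=10)
    params.update(overrides)
    return SimulationConfig(**params)


def full_frame_config(**overrides) -> SimulationConfig:
    """Full instrument frame 404 x 384 (memory-heavy; for spot checks)."""
    params = dict(lines=404, samples=384, fruit_axes=(180, 160),
                  bruise_radius_px=30)
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class GroundTruth:
    """Pixel-level truth for one simulated scan."""

    fruit_mask: np.ndarray
    bruise_mask: np.ndarray
    level: str          # "L1".."L6" or "sound"
    hours: int

    def __post_init__(self):
        self.fruit_mask = np.asarray(self.fruit_mask, dtype=bool)
        self.bruise_mask = np.asarray(self.bruise_mask, dtype=bool)
        if self.fruit_mask.shape != self.bruise_mask.shape:
            raise ValueError("fruit and bruise masks must share a shape")
        if np.any(self.bruise_mask & ~self.fruit_mask):
            raise ValueError("bruise mask must be contained in the fruit mask")


def generate_hypercube(config: SimulationConfig, level: str, hours: int,
                       seed: int) -> tuple[Hypercube, GroundTruth]:
    """Paint one scan: dark background, fruit ellipse, optional bruise disc.

    ``level`` is "sound" or one of L1..L6.  Fruit pixels carry the seeded
    sound spectrum, bruise-disc pixels the bruise spectrum (with a per-fruit
    lognormal amplitude jitter emulating biological variation in bruise
    response), and every pixel receives i.i.d. Gaussian noise per band.
    """
    if level != "sound" and level not in LEVEL_CODES:
        raise ValueError(f"level must be 'sound' or one of {LEVEL_CODES}, got {level!r}")
    grid = config.grid
    wl = np.asarray(grid)
    rng = np.random.default_rng(seed)
    sound = sound_spectrum(grid, seed=int(rng.integers(2 ** 31)),
                           variability_sd=config.fruit_variability_sd,
                           scale_sd=config.fruit_scale_sd)
    # drawn for every cube (also sound ones) to keep the stream layout fixed
    jitter = float(np.exp(rng.normal(0.0, config.amplitude_jitter_sd)))
    det_jitter = float(np.exp(rng.normal(0.0, config.deterioration_jitter_sd)))

    cy, cx = config.lines / 2.0 - 0.5, config.samples / 2.0 - 0.5
    yy, xx = np.ogrid[:config.lines, :config.samples]
    ay, ax = config.fruit_axes
    fruit_mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    r = config.bruise_radius_px
    if level == "sound":
        bruise_mask = np.zeros_like(fruit_mask)
    else:
        bruise_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        bruise_mask &= fruit_mask

    data = np.full((config.lines, config.samples, config.band_count),
                   config.background_reflectance, dtype=np.float64)
    data[fruit_mask] = sound
    if level != "sound":
        energy = level_by_code(level).impact_energy_J
        bruised = bruise_spectrum(
            sound, energy, hours, grid,
            amplitude=config.bruise_amplitude * jitter,
            energy_exponent=config.energy_exponent,
            deterioration_scale=det_jitter,
        )
        data[bruise_mask] = bruised
    # within-fruit tissue heterogeneity: smooth spatial modes times smooth
    # spectral bumps, so ROIs at different positions see different offsets
    if config.tissue_heterogeneity_sd > 0:
        ys = (yy - cy) / max(ay, 1)
        xs = (xx - cx) / max(ax, 1)
        for _ in range(3):
            c = rng.normal(0.0, 1.0, size=5)
            mode = (c[0] * ys + c[1] * xs + c[2] * (ys * xs)
                    + c[3] * (ys ** 2 - 0.5) + c[4] * (xs ** 2 - 0.5))
            mode = mode / max(np.sqrt(np.mean(mode ** 2)), 1e-12)
            centre = rng.uniform(wl[0], wl[-1])
            width = rng.uniform(30.0, 80.0)
            amp = rng.normal(0.0, config.tissue_heterogeneity_sd)
            bump = amp * np.exp(-(((wl - centre) / width) ** 2))
            data += mode[:, :, None] * bump[None, None, :]
    data += rng.normal(0.0, config.noise_sd, size=data.shape)
    np.clip(data, 1e-4, 1.0, out=data)

    cube = Hypercube(data, grid, metadata={
        "level": level, "hours": int(hours), "seed": int(seed),
        "bruise_center_yx": (cy, cx) if level != "sound" else None,
    })
    return cube, GroundTruth(fruit_mask, bruise_mask, level, int(hours))


# --------------------------------------------------------------------------
# Experiment manifests
# --------------------------------------------------------------------------

def _derive_seed(base_seed: int, counter: int) -> int:
    return int((base_seed * 1_000_003 + 7919 * counter + 1) % (2 ** 31))


def replica_manifest(base_seed: int = 0) -> pd.DataFrame:
    """Bookkeeping-faithful manifest: 186 bruised scans per the study design.

    Columns: cube_path (empty until cubes are written), level, hours, batch,
    bruise_index, seed.
    """
    rows = []
    counter = 0
    for level in LEVEL_CODES:
        for batch in (1, 2):
            for hours in REPLICA_SCHEDULE[batch][level]:
                for bruise_index in range(6):
                    rows.append({
                        "cube_path": "", "level": level, "hours": hours,
                        "batch": batch, "bruise_index": bruise_index,
                        "seed": _derive_seed(base_seed, counter),
                    })
                    counter += 1
    return pd.DataFrame(rows)


def full_manifest(base_seed: int = 0, levels=LEVEL_CODES, hours=SCAN_HOURS,
                  n_per_batch: int = 6, batches=(1, 2)) -> pd.DataFrame:
    """Complete-grid manifest: every level scanned at every time point.

    Unlike the truncated study bookkeeping this populates all level x hour
    cells (needed for the 31-class severity problem); defaults give
    6 levels x 5 hours x 12 bruises = 360 scans.
    """
    rows = []
    counter = 0
    for level in levels:
        for h in hours:
            for batch in batches:
                for bruise_index in range(n_per_batch):
                    rows.append({
                        "cube_path": "", "level": level, "hours": h,
                        "batch": batch, "bruise_index": bruise_index,
                        "seed": _derive_seed(base_seed, counter),
                    })
                    counter += 1
    return pd.DataFrame(rows)


def simulate_to_dir(config: SimulationConfig, manifest: pd.DataFrame,
                    out_dir) -> pd.DataFrame:
    """Write every manifest scan as an ENVI cube + PNG masks under ``out_dir``.

    Returns a copy of the manifest with ``cube_path`` filled; also writes it
    as ``manifest.csv``.
    """
    from pathlib import Path

    from .hypercube import write_envi, write_mask

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths = []
    for i, row in manifest.iterrows():
        stem = f"{row.level}_h{row.hours:02d}_b{row.batch}_{row.bruise_index}_{i:04d}"
        cube, truth = generate_hypercube(config, row.level, row.hours, row.seed)
        path = write_envi(cube, out_dir / f"{stem}.raw")
        write_mask(truth.fruit_mask, out_dir / f"{stem}_fruit.png")
        write_mask(truth.bruise_mask, out_dir / f"{stem}_bruise.png")
        paths.append(str(path))
    manifest["cube_path"] = paths
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
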