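"""Synthetic acquisition campaign: drying-curve labels, NIR spectra, leaf images.

The generator emulates the statistical structure of a green-tea fixation
run: 10 sampling points at 25 s intervals, 34 replicate records per point
(340 total), reference moisture falling from 68.17% at 0 s to 15.97% at
225 s along a first-order (exponential) drying curve with replicate
jitter.  Spectra live on a 900-1700 nm grid and carry two water-related
absorption bands, near 1180 nm and 1440 nm, whose depths are affine in the
moisture fraction; reflectance is exp(-absorbance) distorted by a
multiplicative scatter factor, an additive offset and white noise, with
three scans averaged per record, mirroring the acquisition protocol.

Images are square leaf ROIs whose mean colour drifts from bright green
toward a darker yellow-green as moisture falls and whose texture contrast
grows as the leaf dries.  ``fast_mode`` (the default) skips pixel
rendering and emits the 17 image feature variables directly through
affine moisture maps plus noise -- same columns, far cheaper, and what the
test suite runs on; full rendering is exercised by a small smoke test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .image_features import FEATURE_NAMES
from .io import SpectraTable, WavelengthGrid, average_replicate_scans

__all__ = [
    "DryingCurveConfig", "SpectraSimConfig", "BandConfig", "ImageSimConfig",
    "SyntheticDataset", "band_depth", "moisture_curve", "generate_dataset",
]


@dataclass(frozen=True)
class DryingCurveConfig:
    """Exponential drying curve through the two campaign endpoints.

    Moisture means follow m(t) = m0 * exp(-k t) with k fixed by requiring
    m(t_end) = m_end (drying is approximately first order in moisture).
    Replicates scatter around the mean with ``jitter_sd`` (fraction units;
    0.008 = 0.8 percentage points, enough for adjacent time points to
    overlap slightly).
    """

    m0: float = 0.6817
    m_end: float = 0.1597
    n_times: int = 10
    dt_s: float = 25.0
    replicates: int = 34
    jitter_sd: float = 0.008

    def __post_init__(self) -> None:
        if not (self.m0 > self.m_end > 0):
            raise ValueError("need m0 > m_end > 0")
        if self.n_times < 2 or self.replicates < 1 or self.jitter_sd < 0:
            raise ValueError("invalid drying-curve configuration")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) * self.dt_s


def moisture_curve(t_s, cfg: DryingCurveConfig = DryingCurveConfig()) -> np.ndarray:
    """Mean moisture fraction at fixation time t (exponential decay)."""
    t_end = (cfg.n_times - 1) * cfg.dt_s
    k = np.log(cfg.m0 / cfg.m_end) / t_end
    return cfg.m0 * np.exp(-k * np.asarray(t_s, dtype=float))


@dataclass(frozen=True)
class BandConfig:
    """One Gaussian absorption band with depth affine in moisture."""

    center_nm: float
    width_nm: float
    base: float   # depth at zero moisture
    slope: float  # depth increase per unit moisture fraction


def band_depth(moisture_fraction: float, band: BandConfig) -> float:
    """Absorbance depth of a band at the given moisture fraction."""
    return band.base + band.slope * float(moisture_fraction)


@dataclass(frozen=True)
class SpectraSimConfig:
    """Reflectance simulation on the instrument's 900-1700 nm grid."""

    lo_nm: float = 900.0
    hi_nm: float = 1700.0
    step_nm: float = 2.0
    bands: tuple[BandConfig, ...] = (
        BandConfig(1180.0, 40.0, base=0.12, slope=0.35),
        BandConfig(1440.0, 60.0, base=0.10, slope=0.90),
    )
    baseline_level: float = 0.35
    baseline_tilt: float = 2e-4  # absorbance per nm away from 1300 nm
    scatter_sd: float = 0.05    # multiplicative, around 1
    offset_sd: float = 0.02     # additive
    noise_sd: float = 0.005     # white, per channel per scan
    scans_per_sample: int = 3

    def __post_init__(self) -> None:
        if min(self.scatter_sd, self.offset_sd, self.noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.scans_per_sample < 1:
            raise ValueError("need at least one scan per sample")

    @property
    def grid(self) -> WavelengthGrid:
        n = int(round((self.hi_nm - self.lo_nm) / self.step_nm)) + 1
        return WavelengthGrid(self.lo_nm + self.step_nm * np.arange(n))

    def noiseless(self) -> "SpectraSimConfig":
        """Copy with all instrumental noise switched off."""
        d = asdict(self)
        d["bands"] = self.bands
        d.update(scatter_sd=0.0, offset_sd=0.0, noise_sd=0.0)
        return SpectraSimConfig(**d)


def _clean_reflectance(m: float, cfg: SpectraSimConfig, wl: np.ndarray) -> np.ndarray:
    absorb = cfg.baseline_level + cfg.baseline_tilt * (wl - 1300.0)
    for band in cfg.bands:
        absorb = absorb + band_depth(m, band) * np.exp(
            -0.5 * ((wl - band.center_nm) / band.width_nm) ** 2
        )
    return np.exp(-absorb)


@dataclass(frozen=True)
class ImageSimConfig:
    """Leaf-image rendering: moisture-linear colour plus drying texture."""

    roi: int = 1080
    # sRGB endpoints of the mean leaf colour (wet -> dry)
    rgb_wet: tuple[float, float, float] = (60.0, 145.0, 50.0)
    rgb_dry: tuple[float, float, float] = (95.0, 112.0, 45.0)
    texture_amp_wet: float = 6.0    # band-limited noise amplitude, gray units
    texture_amp_dry: float = 22.0   # contrast grows as the leaf dries
    texture_cell_px: int = 8
    pixel_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.roi < 2 * self.texture_cell_px:
            raise ValueError("ROI too small for the texture cell size")


#: affine (intercept, slope-in-moisture, noise sd) maps used by fast_mode.
#: Colour follows the rendered endpoints; texture contrast falls with
#: moisture, matching the rendered band-limited noise.  Noise levels are
#: set so the image modality is informative but clearly weaker than the
#: spectral one, as colour/texture only track moisture indirectly.
_FAST_MAPS: dict[str, tuple[float, float, float]] = {
    "R": (106.0, -67.0, 8.0), "G": (102.0, 63.0, 8.0), "B": (43.0, 10.0, 8.0),
    "H": (85.0, 50.0, 8.0), "S": (0.55, 0.15, 0.04), "V": (0.44, 0.12, 0.04),
    "L": (40.0, 14.0, 2.4), "a": (-14.0, -22.0, 2.4), "b": (38.0, 4.0, 2.4),
    "m": (24.0, 6.0, 2.0), "U": (0.04, 0.05, 0.008), "e": (4.8, -1.2, 0.2),
    "v": (28.0, -18.0, 4.0), "c": (0.78, 0.12, 0.04), "i": (9.0, -7.0, 1.2),
    "IDM": (0.45, 0.25, 0.04), "en": (0.015, 0.02, 0.004),
}


def _render_leaf(m: float, cfg: ImageSimConfig, rng: np.random.Generator) -> np.ndarray:
    u = (m - 0.1597) / (0.6817 - 0.1597)  # 0 = dry endpoint, 1 = wet
    base = (1 - u) * np.asarray(cfg.rgb_dry) + u * np.asarray(cfg.rgb_wet)
    amp = (1 - u) * cfg.texture_amp_dry + u * cfg.texture_amp_wet
    cells = cfg.roi // cfg.texture_cell_px
    coarse = rng.normal(0.0, amp, size=(cells, cells))
    texture = np.kron(coarse, np.ones((cfg.texture_cell_px, cfg.texture_cell_px)))
    texture = texture[: cfg.roi, : cfg.roi]
    img = base[None, None, :] + texture[:, :, None]
    img = img + rng.normal(0.0, cfg.pixel_noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


@dataclass
class SyntheticDataset:
    """Aligned multimodal records from one simulated fixation campaign."""

    spectra: SpectraTable
    image_features: pd.DataFrame  # 17 canonical columns, one row per sample
    images: list | None           # RoiImage arrays when not in fast_mode
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def moisture(self) -> np.ndarray:
        return self.spectra.moisture

    @property
    def time_s(self) -> np.ndarray:
        return self.spectra.time_s


def generate_dataset(
    curve: DryingCurveConfig = DryingCurveConfig(),
    spectra_cfg: SpectraSimConfig = SpectraSimConfig(),
    image_cfg: ImageSimConfig | None = None,
    seed: int = 0,
    fast_mode: bool = True,
) -> SyntheticDataset:
    """Simulate one full acquisition campaign (34 x 10 = 340 records by default).

    ``fast_mode`` emits image feature vectors directly; otherwise leaf ROIs
    are rendered (use a small ``ImageSimConfig.roi`` for tests) and the
    feature table is left to `image_features.extract_all`.
    """
    if image_cfg is None:
        image_cfg = ImageSimConfig(roi=64) if not fast_mode else ImageSimConfig()
    rng = np.random.default_rng(seed)
    wl = spectra_cfg.grid.wavelengths

    times, moisture = [], []
    for t in curve.times:
        mean_m = float(moisture_curve(t, curve))
        reps = rng.normal(mean_m, curve.jitter_sd, size=curve.replicates)
        moisture.extend(np.clip(reps, 1e-6, 1 - 1e-6))
        times.extend([t] * curve.replicates)
    moisture = np.asarray(moisture)
    times = np.asarray(times)
    n = moisture.size

    values = np.empty((n, wl.size))
    for idx in range(n):
        clean = _clean_reflectance(moisture[idx], spectra_cfg, wl)
        scans = []
        for _ in range(spectra_cfg.scans_per_sample):
            mult = rng.normal(1.0, spectra_cfg.scatter_sd)
            offs = rng.normal(0.0, spectra_cfg.offset_sd)
            white = rng.normal(0.0, spectra_cfg.noise_sd, size=wl.size)
            scans.append(mult * clean + offs + white)
        values[idx] = average_replicate_scans(scans)
    if np.any(values < 0):
        raise ValueError(
            "simulation produced negative reflectance; reduce noise/offset levels"
        )

    ids = [f"s{idx:03d}" for idx in range(n)]
    spectra = SpectraTable(ids, spectra_cfg.grid, values, moisture, times)

    images = None
    if fast_mode:
        feats = {
            name: a + b * moisture + rng.normal(0.0, sd, size=n)
            for name, (a, b, sd) in _FAST_MAPS.items()
        }
        table = pd.DataFrame(feats, index=ids)[list(FEATURE_NAMES)]
    else:
        from .image_features import GlcmParams, extract_all

        images = [_render_leaf(m, image_cfg, rng) for m in moisture]
        params = GlcmParams()
        table = pd.DataFrame([extract_all(img, params) for img in images], index=ids)

    snapshot = {
        "curve": asdict(curve),
        "spectra": asdict(spectra_cfg),
        "image": asdict(image_cfg),
        "fast_mode": fast_mode,
    }
    return SyntheticDataset(spectra, table, images, seed, snapshot)
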