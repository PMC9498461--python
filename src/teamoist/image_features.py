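"""The 17 leaf-image feature variables: 9 colour means and 8 texture statistics.

Colour block: mean R, G, B (0-255), mean hue H (degrees, circular mean),
saturation S and value V (0-1), and CIELAB means L*, a*, b* (D65 white
point), all computed per pixel over a fixed rectangular region of interest.

Texture block: from the grey-level histogram p(z) of the ROI -- average grey
level m, uniformity U = sum p^2, entropy e = -sum p log2 p (bits) and
variance v; and from the (symmetric, angle-averaged) grey-level
co-occurrence matrix P(i, j) -- correlation c, inertia (contrast) i,
inverse difference moment IDM and energy en = sum P^2.

Greyscale conversion uses the ITU-R BT.601 luma; grey levels are uniformly
quantized (64 bins over [0, 255] by default) before the co-occurrence
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage.color import rgb2hsv, rgb2lab
from skimage.feature import graycomatrix

__all__ = [
    "FEATURE_NAMES",
    "GlcmParams",
    "load_image",
    "center_roi",
    "extract_color_features",
    "quantize_gray",
    "build_glcm",
    "extract_texture_features",
    "extract_all",
]

#: canonical column order of the 17-variable image feature vector
FEATURE_NAMES = (
    "R", "G", "B", "H", "S", "V", "L", "a", "b",
    "m", "U", "e", "v", "c", "i", "IDM", "en",
)

_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GlcmParams:
    """Grey-level co-occurrence parameters.

    64 quantization levels, unit pixel distance and the four standard angles
    (0, 45, 90, 135 degrees) averaged, with a symmetric normalized matrix.
    """

    levels: int = 64
    distance: int = 1
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 grey levels")
        if self.distance < 1:
            raise ValueError("pixel distance must be >= 1")


def load_image(path) -> np.ndarray:
    """Read an 8-bit RGB raster (BMP or PNG) as an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def center_roi(img: np.ndarray, size: int = 1080) -> np.ndarray:
    """Central size x size crop (the acquisition rig's fixed ROI)."""
    h, w = img.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than ROI {size}x{size}")
    r0, c0 = (h - size) // 2, (w - size) // 2
    return img[r0 : r0 + size, c0 : c0 + size]


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise ValueError("expected a non-empty H x W x 3 RGB image")
    return img


def extract_color_features(img: np.ndarray) -> dict[str, float]:
    """The 9 colour means over the ROI; hue is averaged circularly.

    Hue is an angle, so its mean is taken on the unit circle (vector
    averaging weighted by saturation*value would over-engineer; plain
    vector averaging is used): the arithmetic mean of 350 deg and 10 deg is
    0 deg, not 180 deg.
    """
    img = _validate_rgb(img)
    rgb = img.astype(float)
    R, G, B = (rgb[..., k].mean() for k in range(3))
    hsv = rgb2hsv(img)
    hue_rad = hsv[..., 0] * 2 * np.pi
    hx, hy = np.cos(hue_rad).mean(), np.sin(hue_rad).mean()
    H = float(np.degrees(np.arctan2(hy, hx))) % 360.0
    S, V = hsv[..., 1].mean(), hsv[..., 2].mean()
    lab = rgb2lab(img)
    L, a, b = (lab[..., k].mean() for k in range(3))
    return {
        "R": float(R), "G": float(G), "B": float(B),
        "H": H, "S": float(S), "V": float(V),
        "L": float(L), "a": float(a), "b": float(b),
    }


def quantize_gray(img: np.ndarray, levels: int = 64) -> np.ndarray:
    """BT.601 luma then uniform quantization of [0, 255] into ``levels`` bins."""
    img = _validate_rgb(img)
    luma = img.astype(float) @ _BT601
    q = np.floor(luma * levels / 256.0).astype(np.uint8)
    return np.minimum(q, levels - 1)


def build_glcm(gray: np.ndarray, params: GlcmParams = GlcmParams()) -> np.ndarray:
    """Normalized co-occurrence matrix averaged over the configured angles.

    ``gray`` must already be quantized to ``params.levels``.  Entries are
    joint probabilities (sum to 1); the matrix is symmetric when the
    symmetric flag is set.
    """
    gray = np.asarray(gray)
    if gray.max() >= params.levels:
        raise ValueError("grey image not quantized to params.levels")
    if min(gray.shape) <= params.distance:
        raise ValueError("ROI smaller than the co-occurrence offset")
    angles_rad = [np.deg2rad(a) for a in params.angles]
    counts = graycomatrix(
        gray.astype(np.uint8),
        distances=[params.distance],
        angles=angles_rad,
        levels=params.levels,
        symmetric=params.symmetric,
        normed=False,
    ).astype(float)
    # average over angles, then normalize to probabilities
    P = counts[:, :, 0, :].mean(axis=2)
    total = P.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix")
    return P / total


def extract_texture_features(
    gray: np.ndarray, params: GlcmParams = GlcmParams()
) -> dict[str, float]:
    """The 8 texture statistics (histogram m/U/e/v; co-occurrence c/i/IDM/en)."""
    gray = np.asarray(gray)
    hist = np.bincount(gray.ravel(), minlength=params.levels).astype(float)
    p = hist / hist.sum()
    z = np.arange(params.levels, dtype=float)
    m = float(z @ p)
    U = float(p @ p)
    nz = p[p > 0]
    e = float(-(nz @ np.log2(nz)))
    v = float(((z - m) ** 2) @ p)

    P = build_glcm(gray, params)
    ii, jj = np.meshgrid(z, z, indexing="ij")
    en = float((P * P).sum())
    inertia = float(((ii - jj) ** 2 * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    mu_i = float((ii * P).sum())
    mu_j = float((jj * P).sum())
    sig_i = np.sqrt(((ii - mu_i) ** 2 * P).sum())
    sig_j = np.sqrt(((jj - mu_j) ** 2 * P).sum())
    if sig_i * sig_j < 1e-12:
        import warnings

        warnings.warn("zero GLCM marginal variance; correlation reported as 0")
        corr = 0.0
    else:
        corr = float(((ii - mu_i) * (jj - mu_j) * P).sum() / (sig_i * sig_j))
    return {"m": m, "U": U, "e": e, "v": v, "c": corr, "i": inertia, "IDM": idm, "en": en}


def extract_all(img: np.ndarray, params: GlcmParams = GlcmParams()) -> dict[str, float]:
    """All 17 image feature variables, in the canonical ``FEATURE_NAMES`` order."""
    feats = extract_color_features(img)
    feats.update(extract_texture_features(quantize_gray(img, params.levels), params))
    return {name: feats[name] for name in FEATURE_NAMES}
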