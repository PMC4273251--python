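"""Synthetic ground-truth phantoms and grayscale TIFF I/O.

The phantom generator produces noise-free scenes that mimic the image
classes relevant to photon-limited 2PM of mucosal tissue, on a 12-bit-like
intensity scale (default ceiling 4095):

``cells``
    An epithelial mosaic: Voronoi cells of a few discrete brightness
    classes separated by dark membranes, overlaid with fine multiplicative
    granularity (the mitochondria-packed cytoplasm texture) and a mild
    optical blur.  Texture amplitude 8 % of the local intensity with a
    correlation length of about a pixel -- strong enough to exercise the
    data-adaptive thresholds, fine enough to be at risk of being smoothed
    away.
``particles``
    A dim autofluorescence background (5 % of the ceiling, with gentle
    vignetting and texture) plus a handful of 1-2 pixel bright spots at
    5-10x the background: the quantum-dot nanoparticles whose preservation
    the denoiser is judged on.
``edges``
    Bar gratings and an intensity staircase for sharpness measurements.
``flatfield`` / ``dark``
    Constant-ceiling and all-zero frames for noise calibration.

All generators are pure functions of ``(kind, size, ceiling, seed)``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .types import as_pixels

__all__ = [
    "make_phantom",
    "make_particles_with_positions",
    "default_phantom_suite",
    "read_tiff",
    "write_tiff",
]

PHANTOM_KINDS = ("cells", "particles", "flatfield", "dark", "edges")

#: Detector gain of the emulated instrument, in counts per detected photon.
#: The 12-bit count scale (ceiling 4095) then spans a peak photon budget of
#: about 100 photons per pixel -- the bright end of fast intravital 2PM,
#: with dark structures down at a few photons.
DETECTOR_GAIN = 41.0

# fixed texture/geometry parameters of the generator (the emulated study
# conditions; see docs/methods.md for the reasoning behind each value)
_CELL_AREA_PX = 1100          # about 34 px cell diameter at 0.29 um pixels
_CELL_CLASSES = (0.18, 0.32, 0.50, 0.70)   # brightness classes x ceiling
_MEMBRANE_LEVEL = 0.12        # membrane brightness relative to the cell
_MEMBRANE_WIDTH = 2.0         # px
_GRAIN_STD = 0.08             # granularity amplitude, fraction of local level
_GRAIN_CORR = 1.2             # granularity correlation length, px
_OPTICAL_BLUR = 0.6           # px, mild PSF-like smoothing
_BG_LEVEL = 0.05              # particles: background fraction of ceiling
_SPOT_GAIN = (5.0, 10.0)      # spot amplitude range, x background


def _smooth_noise(rng, size, corr):
    g = gaussian_filter(rng.standard_normal((size, size)), corr, mode="reflect")
    return g / g.std()


def _cells(size, ceiling, rng):
    n = max(6, int(size * size / _CELL_AREA_PX))
    pts = rng.uniform(0, size, (n, 2))
    yy, xx = np.mgrid[0:size, 0:size]
    grid = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    d, idx = cKDTree(pts).query(grid, k=2)
    d = d.reshape(size, size, 2)
    cell_of = idx.reshape(size, size, 2)[:, :, 0]
    levels = np.asarray(_CELL_CLASSES) * ceiling
    brightness = levels[rng.integers(0, len(levels), n)] * rng.normal(1.0, 0.06, n)
    img = brightness[cell_of]
    # dark membranes where the two nearest seeds are equidistant
    border = np.clip((d[:, :, 1] - d[:, :, 0]) / _MEMBRANE_WIDTH, 0.0, 1.0)
    img *= _MEMBRANE_LEVEL + (1.0 - _MEMBRANE_LEVEL) * border**2
    img *= 1.0 + _GRAIN_STD * _smooth_noise(rng, size, _GRAIN_CORR)
    img = gaussian_filter(img, _OPTICAL_BLUR, mode="reflect")
    return np.clip(img, 0.02 * ceiling, 0.95 * ceiling)


def _particles(size, ceiling, rng, k=12):
    bg0 = _BG_LEVEL * ceiling
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = ((yy - size / 2) ** 2 + (xx - size / 2) ** 2) / (size / 2) ** 2
    vignette = 1.15 - 0.30 * r2                       # 0.85 at the corners
    img = bg0 * vignette * (1.0 + _GRAIN_STD * _smooth_noise(rng, size, _GRAIN_CORR))
    margin = 8
    positions: list[tuple[int, int]] = []
    while len(positions) < k:
        r = int(rng.integers(margin, size - margin))
        c = int(rng.integers(margin, size - margin))
        if all((r - pr) ** 2 + (c - pc) ** 2 >= 12**2 for pr, pc in positions):
            amp = rng.uniform(*_SPOT_GAIN) * bg0
            img[r, c] += amp
            if rng.random() < 0.5:  # two-pixel particle
                dr, dc = rng.choice([(-1, 0), (1, 0), (0, -1), (0, 1)])
                img[r + dr, c + dc] += 0.5 * amp
            positions.append((r, c))
    return img, positions


def _edges(size, ceiling):
    img = np.full((size, size), 0.1 * ceiling)
    half = size // 2
    # left half: vertical bar gratings of growing pitch
    col = 0
    width = 2
    hi = True
    while col < half:
        w = min(width, half - col)
        img[:, col : col + w] = (0.8 if hi else 0.15) * ceiling
        col += w
        hi = not hi
        if not hi:
            width = min(width + 1, 8)
    # right half: intensity staircase
    steps = 8
    rows = np.array_split(np.arange(size), steps)
    for i, rr in enumerate(rows):
        img[rr, half:] = (0.1 + 0.8 * i / (steps - 1)) * ceiling
    return img


def make_phantom(kind: str, size: int = 256, intensity_ceiling: float = 4095.0, seed: int = 0):
    """Generate a noise-free ground-truth phantom.

    Deterministic in ``(kind, size, intensity_ceiling, seed)``.  ``cells``
    and ``particles`` require ``size >= 64``.
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; expected one of {PHANTOM_KINDS}")
    if size < 1:
        raise ValueError("size must be positive")
    if kind in ("cells", "particles") and size < 64:
        raise ValueError(f"{kind} phantoms require size >= 64, got {size}")
    rng = np.random.default_rng(seed)
    if kind == "flatfield":
        return np.full((size, size), float(intensity_ceiling))
    if kind == "dark":
        return np.zeros((size, size))
    if kind == "edges":
        return _edges(size, intensity_ceiling)
    if kind == "cells":
        return _cells(size, intensity_ceiling, rng)
    img, _ = _particles(size, intensity_ceiling, rng)
    return img


def make_particles_with_positions(
    size: int = 256, intensity_ceiling: float = 4095.0, seed: int = 0, k: int = 12
):
    """Particles phantom together with the seeded spot centres.

    Same pixels as ``make_phantom('particles', ...)`` for the default ``k``.
    """
    if size < 64:
        raise ValueError("particles phantoms require size >= 64")
    rng = np.random.default_rng(seed)
    return _particles(size, intensity_ceiling, rng, k=k)


def default_phantom_suite(size: int = 256, intensity_ceiling: float = 4095.0, seed: int = 0):
    """The 10-phantom evaluation suite: 4 cells, 3 particles, 2 edges, 1 flat.

    A desk-scale stand-in for a set of high-quality averaged acquisitions
    declared as ground truth.
    """
    kinds = ["cells"] * 4 + ["particles"] * 3 + ["edges"] * 2 + ["flatfield"]
    return [
        make_phantom(kind, size, intensity_ceiling, seed=seed + i)
        for i, kind in enumerate(kinds)
    ]


def read_tiff(path) -> list[np.ndarray]:
    """Read a grayscale (multi-page) TIFF as a list of float 2-D arrays."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
    out = []
    for i, page in enumerate(pages):
        arr = np.asarray(page)
        if arr.ndim != 2:
            raise ValueError(
                f"page {i} of {path.name} is not single-channel grayscale "
                f"(shape {arr.shape})"
            )
        out.append(arr.astype(np.float64))
    return out


def write_tiff(path, images, bit_depth: int = 16) -> int:
    """Write one image or a list of images as a grayscale multi-page TIFF.

    Values outside the representable range are clipped; the number of
    clipped pixels is returned and reported as a warning.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    if isinstance(images, (list, tuple)):
        arrays = [as_pixels(im) for im in images]
    else:
        arrays = [as_pixels(images)]
    top = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    clipped = 0
    pages = []
    for arr in arrays:
        out_of_range = (arr < 0) | (arr > top)
        clipped += int(out_of_range.sum())
        pages.append(np.clip(np.rint(arr), 0, top).astype(dtype))
    if clipped:
        warnings.warn(f"{clipped} pixel(s) clipped to the {bit_depth}-bit range")
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    return clipped
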