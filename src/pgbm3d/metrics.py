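"""Full-reference image-quality metrics used by the evaluation harness.

MSE, multiscale structural similarity (MS-SSIM) with the published default
parameters of the multiscale SSIM reference (exponent weights 0.0448,
0.2856, 0.3001, 0.2363, 0.1333; 11x11 Gaussian window with sigma 1.5;
stability constants K1 = 0.01, K2 = 0.03), and a gradient-energy sharpness
index of the kind used for automated microscope focusing.  The sharpness
index is only meaningful comparatively (between reconstructions of the same
scene), which is how the evaluation uses it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import sobel
from scipy.signal import fftconvolve

from .types import as_pixels

__all__ = ["mse", "ms_ssim", "sharpness_index", "relative_curves"]

#: Per-scale exponent weights of the 5-scale MS-SSIM.
MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)
_WIN = 11
_SIGMA = 1.5


def mse(a, b) -> float:
    """Mean squared error between two equally shaped images."""
    x = as_pixels(a)
    y = as_pixels(b)
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    return float(np.mean((x - y) ** 2))


def _gaussian_kernel(win: int, sigma: float) -> np.ndarray:
    r = np.arange(win) - (win - 1) / 2.0
    g = np.exp(-(r**2) / (2 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def _ssim_terms(a, b, dynamic_range, k1, k2):
    kern = _gaussian_kernel(_WIN, _SIGMA)
    mu1 = fftconvolve(a, kern, mode="valid")
    mu2 = fftconvolve(b, kern, mode="valid")
    s11 = fftconvolve(a * a, kern, mode="valid") - mu1**2
    s22 = fftconvolve(b * b, kern, mode="valid") - mu2**2
    s12 = fftconvolve(a * b, kern, mode="valid") - mu1 * mu2
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    lum = (2 * mu1 * mu2 + c1) / (mu1**2 + mu2**2 + c1)
    cs = (2 * s12 + c2) / (s11 + s22 + c2)
    return float(lum.mean()), float(cs.mean())


def _downsample2(x: np.ndarray) -> np.ndarray:
    h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    x = x[:h, :w]
    return (x[0::2, 0::2] + x[0::2, 1::2] + x[1::2, 0::2] + x[1::2, 1::2]) / 4.0


def ms_ssim(
    a,
    b,
    dynamic_range: float,
    weights=MS_SSIM_WEIGHTS,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Multiscale structural similarity between *a* and *b*.

    Contrast/structure terms are combined across ``len(weights)`` dyadic
    scales (2x2 mean-pool between scales) with the luminance term applied at
    the coarsest scale only; each factor enters with its exponent weight.
    Identical images score exactly 1.

    Raises
    ------
    ValueError
        If the images are too small for the requested number of scales (the
        minimum side is ``11 * 2**(scales-1)`` pixels) or shapes/range are
        invalid.
    """
    x = as_pixels(a)
    y = as_pixels(b)
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    if not dynamic_range > 0:
        raise ValueError("dynamic_range must be positive")
    scales = len(weights)
    min_side = _WIN * 2 ** (scales - 1)
    if min(x.shape) < min_side:
        raise ValueError(
            f"image of shape {x.shape} is too small for {scales} scales; "
            f"each side must be at least {min_side} pixels"
        )
    value = 1.0
    for s in range(scales):
        lum, cs = _ssim_terms(x, y, dynamic_range, k1, k2)
        term = lum * cs if s == scales - 1 else cs
        if term <= 0:
            return 0.0  # strongly anticorrelated structure; degenerate case
        value *= term ** weights[s]
        if s < scales - 1:
            x = _downsample2(x)
            y = _downsample2(y)
    return float(value)


def sharpness_index(img) -> float:
    """Gradient-energy sharpness: mean squared Sobel gradient magnitude,
    normalized by the mean squared intensity so the measure is gain
    invariant.  Zero for constant images; higher values mean sharper."""
    x = as_pixels(img)
    denom = float(np.mean(x**2))
    if denom == 0.0:
        return 0.0
    gx = sobel(x, axis=1, mode="reflect")
    gy = sobel(x, axis=0, mode="reflect")
    return float(np.mean(gx**2 + gy**2) / denom)


def relative_curves(results: pd.DataFrame) -> pd.DataFrame:
    """Modified-vs-original ratios per (phantom, alpha) pair.

    Expects the long-format table produced by
    :func:`pgbm3d.pipeline.evaluate_curves` and returns one row per pair
    with ``mse_ratio`` and ``ms_ssim_ratio`` (modified / original) and
    ``si_pct_diff`` (percent difference of the sharpness index).

    Raises
    ------
    ValueError
        If any (phantom, alpha) cell lacks exactly one row per mode.
    """
    required = {"phantom_id", "alpha", "mode", "mse", "ms_ssim", "si"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")
    rows = []
    for (pid, alpha), grp in results.groupby(["phantom_id", "alpha"], sort=True):
        modes = grp.set_index("mode")
        if set(modes.index) != {"modified", "original"} or len(grp) != 2:
            raise ValueError(
                f"phantom {pid} at alpha {alpha} is not a modified/original pair"
            )
        mod, orig = modes.loc["modified"], modes.loc["original"]
        si_base = orig["si"] if orig["si"] != 0 else np.nan
        rows.append(
            {
                "phantom_id": pid,
                "alpha": alpha,
                "mse_ratio": mod["mse"] / orig["mse"] if orig["mse"] else np.nan,
                "ms_ssim_ratio": mod["ms_ssim"] / orig["ms_ssim"]
                if orig["ms_ssim"]
                else np.nan,
                "si_pct_diff": 100.0 * (mod["si"] - orig["si"]) / si_base,
            }
        )
    return pd.DataFrame(rows)
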