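"""Noise suppression inside a transformed block group, and aggregation.

Level 1 applies hard thresholding to the 3-D transform coefficients of each
group.  Two flavors exist:

``bayes``
    The data-adaptive threshold, computed separately per subband: with
    coefficient noise level ``sigma`` and subband signal estimate

        sigma_y = sqrt( max( mean(c^2) - sigma^2, 0 ) )

    (Chang et al.'s BayesShrink estimator, assuming zero-mean detail
    coefficients) the threshold is ``Th_Bayes = sigma^2 / sigma_y``.  A
    subband with no detectable signal energy (``sigma_y = 0``) is zeroed
    entirely (threshold +inf).  The thresholding itself stays *hard*.
``fixed``
    The original-BM3D baseline, a single threshold ``lambda * sigma``
    (``lambda = 2.7``) on all detail coefficients.

The scaling x scaling subband is never thresholded in either flavor: it
carries the local mean, for which the zero-mean Bayes estimate is undefined.
Coefficients equal to the threshold survive (strict ``|c| < th`` is zeroed).

Level 2 replaces thresholding by empirical Wiener shrinkage
``W = P^2 / (P^2 + sigma^2)`` with the pilot coefficient ``P`` taken from
the transformed basic estimate.

Filtered blocks are returned to their positions and averaged with per-group
weights (``1/retained`` for hard thresholding, ``1/sum(W^2)`` for Wiener),
the usual sparsity-rewarding aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .transforms import SubbandMap

__all__ = [
    "FilterResult",
    "bayes_threshold",
    "hard_threshold_stack",
    "wiener_filter_stack",
    "aggregate",
]

#: Floor for Wiener aggregation weights' denominator.
WIENER_ENERGY_FLOOR = 1e-12


@dataclass
class FilterResult:
    """Filtered pixel-domain stack plus its aggregation bookkeeping."""

    stack: np.ndarray          # block_size x block_size x n_blocks, pixel domain
    weight: float              # positive aggregation weight of this group
    retained_count: int        # non-zeroed coefficients (hard) / energy proxy

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError("aggregation weight must be positive")


def bayes_threshold(subband_coefficients, sigma: float) -> float:
    """Per-subband data-adaptive hard threshold ``sigma^2 / sigma_y``.

    Returns ``+inf`` when the subband's estimated signal deviation is zero,
    meaning the whole subband is noise and will be zeroed.
    """
    c = np.asarray(subband_coefficients, dtype=float).ravel()
    if c.size == 0:
        raise ValueError("subband must be non-empty")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    sigma_z_sq = float(np.mean(c**2))
    sigma_y = np.sqrt(max(sigma_z_sq - sigma**2, 0.0))
    if sigma_y == 0.0:
        return np.inf
    return sigma**2 / sigma_y


def _band_thresholds(
    coeffs: np.ndarray, smap: SubbandMap, sigma: float, mode: str, lam: float
) -> np.ndarray:
    """Threshold per subband id; the protected scaling band gets 0."""
    n_bands = smap.n_subbands
    th = np.zeros(n_bands)
    if mode == "bayes":
        if sigma > 0:
            sq = coeffs**2
            sums = np.bincount(smap.labels.ravel(), weights=sq.ravel(), minlength=n_bands)
            mean_sq = sums / smap.sizes
            sigma_y = np.sqrt(np.maximum(mean_sq - sigma**2, 0.0))
            with np.errstate(divide="ignore"):
                th = np.where(sigma_y > 0, sigma**2 / np.maximum(sigma_y, 1e-300), np.inf)
        # sigma == 0: thresholds stay 0, nothing is zeroed
    elif mode == "fixed":
        th = np.full(n_bands, lam * sigma)
    else:
        raise ValueError(f"unknown hard-threshold mode {mode!r}; expected 'bayes' or 'fixed'")
    th[smap.protected] = 0.0
    return th


def hard_threshold_stack(
    coefficients,
    smap: SubbandMap,
    sigma: float,
    mode: str = "bayes",
    lam: float = 2.7,
) -> tuple[np.ndarray, int]:
    """Hard-threshold a transformed group per subband.

    Returns the thresholded coefficients and the retained coefficient count
    (used for the aggregation weight).
    """
    c = np.asarray(coefficients, dtype=float)
    if c.shape != smap.labels.shape:
        raise ValueError(
            f"coefficient shape {c.shape} does not match subband map {smap.labels.shape}"
        )
    th_bands = _band_thresholds(c, smap, sigma, mode, lam)
    th_per_coeff = th_bands[smap.labels]
    keep = ~(np.abs(c) < th_per_coeff)  # equality survives
    out = np.where(keep, c, 0.0)
    return out, int(keep.sum())


def wiener_filter_stack(noisy_coefficients, pilot_coefficients, sigma: float):
    """Empirical Wiener shrinkage of a noisy stack against a pilot stack.

    ``W = P^2 / (P^2 + sigma^2)`` per coefficient; returns the shrunk
    coefficients and the Wiener energy ``sum(W^2)`` whose reciprocal is the
    aggregation weight.
    """
    cn = np.asarray(noisy_coefficients, dtype=float)
    cp = np.asarray(pilot_coefficients, dtype=float)
    if cn.shape != cp.shape:
        raise ValueError(f"coefficient shapes differ: {cn.shape} vs {cp.shape}")
    p2 = cp**2
    denom = p2 + sigma**2
    w = np.divide(p2, denom, out=np.zeros_like(p2), where=denom > 0)
    return w * cn, float(np.sum(w**2))


def aggregate(
    groups: Iterable[tuple[FilterResult, Sequence]],
    image_shape: tuple[int, int],
    fallback=None,
) -> np.ndarray:
    """Weighted averaging of overlapping block-wise estimates.

    Each entry pairs a :class:`FilterResult` with the (row, col) top-left
    coordinates of its blocks.  Pixels covered by no block are copied from
    ``fallback`` when given, else left at zero.
    """
    h, w = image_shape
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    for result, coords in groups:
        stack = np.asarray(result.stack, dtype=float)
        b = stack.shape[0]
        for k, (r, c) in enumerate(np.asarray(coords, dtype=np.intp)):
            if not (0 <= r <= h - b and 0 <= c <= w - b):
                raise ValueError(f"block at ({r}, {c}) falls outside image {image_shape}")
            num[r : r + b, c : c + b] += result.weight * stack[:, :, k]
            den[r : r + b, c : c + b] += result.weight
    covered = den > 0
    out = np.zeros((h, w))
    out[covered] = num[covered] / den[covered]
    if fallback is not None:
        fb = np.asarray(fallback, dtype=float)
        out[~covered] = fb[~covered]
    return out
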