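"""Signal-dependent Poisson-Gaussian noise model for 2-photon microscopy.

At the low photon counts of intravital 2PM the detected signal is dominated
by shot noise, which is Poisson distributed with a variance that grows with
the underlying fluorescence intensity.  On top of that the detection chain
adds a signal-independent Gaussian component (readout noise and offset).
The measured image is modelled as

    z(x) = alpha * eta_p(x) + eta_G(x),      eta_p(x) ~ Poisson(y(x)),
                                             eta_G(x) ~ N(mu_G, sigma_G^2),

with ``alpha > 0`` the detector gain (counts per detected photon) and
``y(x) >= 0`` the noise-free photon rate.  The first two moments are

    E[z]   = alpha * y + mu_G
    Var[z] = alpha^2 * y + sigma_G^2,

i.e. the variance is an affine function of the mean -- the heteroscedastic
signature this module both simulates and calibrates:

    Var = alpha * (E[z] - mu_G) + sigma_G^2.

Calibration follows the standard microscope procedure: *dark frames*
(zero excitation) isolate the Gaussian component, a *flat-field ladder*
(homogeneous fluorescent slide imaged at step-wise increasing laser power)
exposes the linear variance/mean relation whose slope is ``alpha``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import as_pixels

__all__ = [
    "NoiseParams",
    "CalibrationSeries",
    "simulate_pg_noise",
    "estimate_noise_variance",
    "estimate_gaussian_params",
    "calibrate_alpha",
    "variance_vs_intensity_curve",
]


@dataclass(frozen=True)
class NoiseParams:
    """Parameters of the mixed Poisson-Gaussian noise model.

    Attributes
    ----------
    alpha:
        Positive scale factor (detector counts per detected photon).
    mu_g:
        Mean of the Gaussian (signal-independent) component, in counts.
    sigma_g:
        Standard deviation of the Gaussian component, in counts.
    """

    alpha: float
    mu_g: float = 0.0
    sigma_g: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.sigma_g < 0:
            raise ValueError(f"sigma_g must be non-negative, got {self.sigma_g}")

    def mean(self, y):
        """Expected measured value for photon rate ``y``."""
        return self.alpha * np.asarray(y, dtype=float) + self.mu_g

    def variance(self, y):
        """Noise variance for photon rate ``y``: ``alpha^2 y + sigma_g^2``."""
        return self.alpha**2 * np.asarray(y, dtype=float) + self.sigma_g**2

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "mu_g": self.mu_g, "sigma_g": self.sigma_g}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseParams":
        return cls(alpha=float(d["alpha"]), mu_g=float(d["mu_g"]), sigma_g=float(d["sigma_g"]))


@dataclass
class CalibrationSeries:
    """A noise-calibration data set: flat-field frames plus dark frames.

    ``flats`` holds homogeneous (constant ground-truth) images, optionally
    annotated with their excitation level; ``darks`` holds frames recorded at
    zero excitation, whose expected signal is zero.
    """

    flats: list = field(default_factory=list)
    levels: list = field(default_factory=list)
    darks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.flats = [as_pixels(f) for f in self.flats]
        if not self.levels:
            self.levels = [None] * len(self.flats)
        if len(self.levels) != len(self.flats):
            raise ValueError("levels must be empty or match flats in length")
        self.darks = [as_pixels(d) for d in self.darks]

    @classmethod
    def from_directory(cls, directory, manifest) -> "CalibrationSeries":
        """Load a series from TIFF files and a JSON manifest.

        The manifest maps file name -> excitation level; frames with level 0
        are treated as dark frames.
        """
        from .phantoms_io import read_tiff

        directory = Path(directory)
        with open(manifest) as fh:
            mapping = json.load(fh)
        flats, levels, darks = [], [], []
        for name, level in sorted(mapping.items()):
            pages = read_tiff(directory / name)
            for page in pages:
                if float(level) == 0.0:
                    darks.append(page)
                else:
                    flats.append(page)
                    levels.append(float(level))
        return cls(flats=flats, levels=levels, darks=darks)


def simulate_pg_noise(ground_truth, params: NoiseParams, seed: int) -> np.ndarray:
    """Draw one noisy realization ``z = alpha*Poisson(y) + N(mu_G, sigma_G^2)``.

    Every pixel is drawn independently; the result is deterministic for a
    given ``seed``.  Non-integer photon rates are allowed (the Poisson rate is
    real-valued).

    Raises
    ------
    ValueError
        If any ground-truth pixel is negative (the offending pixel is named)
        or if ``params.alpha`` is not positive.
    """
    y = as_pixels(ground_truth)
    neg = np.argwhere(y < 0)
    if neg.size:
        r, c = neg[0]
        raise ValueError(
            f"ground truth must be non-negative; pixel ({r}, {c}) = {y[r, c]!r}"
        )
    rng = np.random.default_rng(seed)
    z = params.alpha * rng.poisson(y).astype(np.float64)
    z += rng.normal(params.mu_g, params.sigma_g, size=y.shape)
    return z


def estimate_noise_variance(flat_field) -> float:
    """Population variance of a homogeneous frame.

    For a flat-field image the ground truth is constant, so subtracting the
    mean intensity isolates the noise; the estimator is
    ``(1/|X|) * sum_x (z(x) - mean(z))^2`` (population normalization by the
    pixel count ``|X|``).
    """
    z = as_pixels(flat_field)
    return float(np.var(z))


def estimate_gaussian_params(dark_images: Sequence) -> tuple[float, float]:
    """Estimate ``(mu_G, sigma_G)`` from dark frames.

    Dark frames are recorded at zero excitation, so the Poisson term vanishes
    and the pixel statistics are those of the Gaussian component alone.  The
    statistics are pooled over the concatenation of all pixels of all frames.
    """
    if not dark_images:
        raise ValueError("at least one dark image is required")
    pooled = np.concatenate([as_pixels(d).ravel() for d in dark_images])
    return float(pooled.mean()), float(pooled.std())


def calibrate_alpha(
    series: CalibrationSeries, gaussian: tuple[float, float]
) -> tuple[float, float]:
    """Fit the gain ``alpha`` from the flat-field variance/mean relation.

    Fits ``Var = alpha * (mean - mu_G) + sigma_G^2`` by ordinary least squares
    with ``(mu_G, sigma_G)`` held fixed at the dark-frame estimates; returns
    the slope ``alpha`` and the coefficient of determination R^2 of the fit.

    Raises
    ------
    ValueError
        If fewer than two flat-field frames are given or all their mean
        intensities coincide (degenerate fit).
    """
    mu_g, sigma_g = float(gaussian[0]), float(gaussian[1])
    if len(series.flats) < 2:
        raise ValueError("at least 2 flat-field levels are required to fit alpha")
    means = np.array([as_pixels(f).mean() for f in series.flats])
    variances = np.array([estimate_noise_variance(f) for f in series.flats])
    x = means - mu_g
    if np.ptp(means) == 0:
        raise ValueError("all flat-field means are identical; cannot fit a slope")
    yv = variances - sigma_g**2
    alpha = float(x @ yv / (x @ x))
    fitted = alpha * x + sigma_g**2
    ss_res = float(np.sum((variances - fitted) ** 2))
    ss_tot = float(np.sum((variances - variances.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return alpha, r2


def variance_vs_intensity_curve(
    series: CalibrationSeries, params: NoiseParams | None = None
) -> pd.DataFrame:
    """Tabulate estimated vs model-predicted noise variance per flat-field level.

    Returns a DataFrame with columns ``(mean, var_est, var_model)``, one row
    per flat-field frame.  ``var_model`` evaluates the calibrated model
    ``alpha * (mean - mu_G) + sigma_G^2``; it is ``NaN`` when *params* is not
    given.  Export with ``df.to_csv(path, index=False)``.
    """
    rows = []
    for flat in series.flats:
        m = float(as_pixels(flat).mean())
        v = estimate_noise_variance(flat)
        if params is None:
            pred = float("nan")
        else:
            pred = params.alpha * (m - params.mu_g) + params.sigma_g**2
        rows.append((m, v, pred))
    return pd.DataFrame(rows, columns=["mean", "var_est", "var_model"])
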