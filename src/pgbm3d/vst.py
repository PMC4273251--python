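"""Variance stabilization for Poisson-Gaussian data.

The generalized Anscombe root transformation

    f(z) = (2/alpha) * sqrt( alpha*z + (3/8)*alpha^2 + sigma_G^2 - alpha*mu_G )

maps measurements following the mixed Poisson-Gaussian model to a domain in
which the noise is approximately additive white Gaussian with unit variance,
so a denoiser designed for AWGN can be applied.  The radicand is clamped at
zero so that dark pixels below the offset remain finite.

Going back to the intensity domain is the delicate part.  Three inverses are
provided:

``algebraic``
    Exact function inversion of ``f``; returns the *measured-domain* value
    ``z`` with ``f(z) = D``.  Biased as an estimator of the photon rate.
``asymptotic``
    The algebraic inverse plus the classical unbiasing correction (the
    ``-1/8`` vs ``-3/8`` rate-domain constant, i.e. ``+alpha/4`` in counts);
    unbiased to first order for large rates.
``exact_unbiased``
    Defined through the conditional expectation ``y -> E[f(z) | y]``,
    tabulated on a grid and inverted by monotone interpolation.  This is the
    default: it removes the low-count bias of the closed-form inverses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .noise_model import NoiseParams
from .types import as_pixels

__all__ = [
    "VSTSpec",
    "generalized_anscombe",
    "build_exact_inverse_table",
    "exact_unbiased_inverse",
    "asymptotic_inverse",
    "algebraic_inverse",
]

#: Poisson tail mass discarded when truncating the expectation sum.
_POISSON_TAIL = 1e-12
#: Number of Gauss-Hermite nodes used for the Gaussian part of E[f(z)|y].
_GH_NODES = 41


def generalized_anscombe(z, params: NoiseParams) -> np.ndarray:
    """Apply the generalized Anscombe root transformation to ``z``.

    After the transform the noise is approximately unit-variance AWGN for
    rates that are not extremely small.
    """
    zz = as_pixels(z) if np.ndim(z) == 2 else np.asarray(z, dtype=float)
    a = params.alpha
    radicand = a * zz + 0.375 * a**2 + params.sigma_g**2 - a * params.mu_g
    return (2.0 / a) * np.sqrt(np.maximum(radicand, 0.0))


def algebraic_inverse(stabilized, params: NoiseParams) -> np.ndarray:
    """Exact inversion of the forward formula; returns measured-domain ``z``.

    ``algebraic_inverse(generalized_anscombe(z)) == z`` wherever the forward
    radicand was positive; inputs below zero are clamped to the clip point.
    """
    d = np.maximum(np.asarray(stabilized, dtype=float), 0.0)
    a = params.alpha
    return a * (d / 2.0) ** 2 - 0.375 * a - params.sigma_g**2 / a + params.mu_g


def asymptotic_inverse(stabilized, params: NoiseParams) -> np.ndarray:
    """Algebraic inverse plus the first-order unbiasing correction (+alpha/4).

    In rate units this is the classical ``(D/2)^2 - 1/8`` inverse (instead of
    the algebraic ``-3/8``), generalized to the Poisson-Gaussian transform.
    Returns measured-domain counts, like :func:`algebraic_inverse`.
    """
    return algebraic_inverse(stabilized, params) + params.alpha / 4.0


def _rate_from_counts(counts, params: NoiseParams) -> np.ndarray:
    """Convert noise-free measured-domain counts to a photon rate estimate."""
    return np.maximum((np.asarray(counts, dtype=float) - params.mu_g) / params.alpha, 0.0)


@dataclass
class VSTSpec:
    """Frozen description of a variance-stabilizing transform and its inverse.

    Holds the noise parameters together with the tabulated forward
    expectation ``E[f(z) | y]`` on a strictly increasing rate grid, which
    defines the exact unbiased inverse.  Serializable to JSON so that runs
    are bit-reproducible.
    """

    params: NoiseParams
    y_grid: np.ndarray
    expected: np.ndarray
    inverse_kind: str = "exact_unbiased"

    def __post_init__(self) -> None:
        self.y_grid = np.asarray(self.y_grid, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        if self.y_grid.ndim != 1 or self.y_grid.shape != self.expected.shape:
            raise ValueError("y_grid and expected must be 1-D arrays of equal length")
        if not (np.all(np.diff(self.y_grid) > 0) and np.all(np.diff(self.expected) > 0)):
            raise ValueError("inverse table must be strictly increasing in both columns")

    def interpolator(self) -> PchipInterpolator:
        # monotone piecewise-cubic inverse: expected value -> rate
        return PchipInterpolator(self.expected, self.y_grid, extrapolate=False)

    def to_json(self, path) -> None:
        payload = {
            "params": self.params.to_dict(),
            "inverse_kind": self.inverse_kind,
            "y_grid": self.y_grid.tolist(),
            "expected": self.expected.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "VSTSpec":
        payload = json.loads(Path(path).read_text())
        return cls(
            params=NoiseParams.from_dict(payload["params"]),
            y_grid=np.asarray(payload["y_grid"]),
            expected=np.asarray(payload["expected"]),
            inverse_kind=payload.get("inverse_kind", "exact_unbiased"),
        )


def _expected_forward(y: float, params: NoiseParams, nodes, weights) -> float:
    """Numerical expectation E[f(z) | y] under the Poisson-Gaussian law.

    The Poisson sum is truncated where the tail mass drops below 1e-12; the
    Gaussian integral is evaluated by Gauss-Hermite quadrature (analytically
    exact when sigma_G = 0).
    """
    a = params.alpha
    if y <= 0:
        ks = np.array([0])
        pmf = np.array([1.0])
    else:
        lo = int(stats.poisson.ppf(_POISSON_TAIL, y))
        hi = int(stats.poisson.ppf(1.0 - _POISSON_TAIL, y)) + 1
        ks = np.arange(lo, hi + 1)
        pmf = stats.poisson.pmf(ks, y)
    if params.sigma_g > 0:
        g = params.mu_g + np.sqrt(2.0) * params.sigma_g * nodes
        z = a * ks[:, None] + g[None, :]
        fz = generalized_anscombe(z, params)
        inner = fz @ weights / np.sqrt(np.pi)
    else:
        z = a * ks + params.mu_g
        inner = generalized_anscombe(z, params)
    return float(pmf @ inner)


def build_exact_inverse_table(params: NoiseParams, y_grid) -> VSTSpec:
    """Tabulate ``E[f(z) | y]`` over *y_grid* and return the resulting spec.

    Raises
    ------
    ValueError
        If the grid is not strictly increasing or the computed table fails to
        be strictly monotone (a numerical failure; diagnostics are included).
    """
    y_grid = np.asarray(y_grid, dtype=float)
    if y_grid.ndim != 1 or y_grid.size < 2 or not np.all(np.diff(y_grid) > 0):
        raise ValueError("y_grid must be a strictly increasing 1-D array")
    nodes, weights = np.polynomial.hermite.hermgauss(_GH_NODES)
    expected = np.array([_expected_forward(y, params, nodes, weights) for y in y_grid])
    steps = np.diff(expected)
    if not np.all(steps > 0):
        bad = int(np.argmin(steps))
        raise ValueError(
            "expected-forward table is not strictly increasing "
            f"(first violation between y={y_grid[bad]} and y={y_grid[bad + 1]}: "
            f"E={expected[bad]} -> {expected[bad + 1]})"
        )
    return VSTSpec(params=params, y_grid=y_grid, expected=expected)


def default_rate_grid(max_rate: float, n: int = 512) -> np.ndarray:
    """Log-spaced rate grid on [0, 1.5 * max_rate] for the inverse table."""
    top = 1.5 * max(float(max_rate), 1.0)
    lo = min(1e-2, top / 1e4)
    grid = np.concatenate([[0.0], np.geomspace(lo, top, n - 1)])
    return grid


def exact_unbiased_inverse(stabilized, spec: VSTSpec) -> np.ndarray:
    """Map stabilized values back to photon rates via the tabulated inverse.

    Values below the table minimum map to rate 0; values above the maximum
    use the asymptotic inverse continuation (which the exact inverse
    approaches for large rates).
    """
    d = np.asarray(as_pixels(stabilized) if np.ndim(stabilized) == 2 else stabilized, dtype=float)
    params = spec.params
    out = np.zeros_like(d, dtype=float)
    lo, hi = spec.expected[0], spec.expected[-1]
    inside = (d >= lo) & (d <= hi)
    if np.any(inside):
        out[inside] = spec.interpolator()(d[inside])
    above = d > hi
    if np.any(above):
        out[above] = _rate_from_counts(asymptotic_inverse(d[above], params), params)
    return np.maximum(out, 0.0)
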