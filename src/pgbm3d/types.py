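"""Light-weight containers shared across the package.

All numerical routines in :mod:`pgbm3d` accept plain 2-D :class:`numpy.ndarray`
objects; :class:`Image` is a thin wrapper that additionally carries a *role*
tag so that pipelines and I/O code can state whether an array holds raw
detector counts ``z(x)``, a noise-free ground truth ``y(x)``, a
variance-stabilized signal, or a reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Valid role tags for :class:`Image`.
ROLES = ("ground_truth", "measured", "stabilized", "estimate")


@dataclass
class Image:
    """A single-channel 2-D intensity raster.

    Parameters
    ----------
    pixels:
        2-D array of real intensities.  Detector counts for raw/ground-truth
        data, stabilized units after the variance-stabilizing transform.
    role:
        One of :data:`ROLES`; purely informational.
    """

    pixels: np.ndarray
    role: str = "measured"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("Image requires a non-empty 2-D pixel array")
        if self.role not in ROLES:
            raise ValueError(f"unknown image role {self.role!r}; expected one of {ROLES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def as_pixels(image) -> np.ndarray:
    """Return the 2-D float array behind *image* (``Image`` or array-like)."""
    if isinstance(image, Image):
        return image.pixels
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D image array")
    return arr
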