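"""Sparse-domain transforms for collaborative filtering.

Grouped blocks are filtered in a separable 3-D wavelet domain: an orthonormal
2-D Haar analysis of each block followed by an orthonormal 1-D Haar transform
along the stack axis.

For the 2-D part the *non-standard* decomposition is used: at every level one
Haar step is applied to the rows and one to the columns of the current
low-pass quadrant, and the recursion continues on that quadrant (the familiar
pyramid scheme).  Compared with the *standard* decomposition (all rows to
full depth, then all columns), this yields a coarser partition into subbands
with more coefficients each -- which is what makes per-subband statistics
such as the BayesShrink signal estimate reliable.

Subbands of the full 3-D coefficient array are labelled by the cross product
(2-D level, orientation) x (stack scale).  All transforms here are
orthonormal, so unit-variance white noise in the pixel domain stays
unit-variance per coefficient -- the property the thresholding stage relies
on.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "SubbandMap",
    "haar2d_nonstandard_forward",
    "haar2d_nonstandard_inverse",
    "haar2d_standard_forward",
    "haar1d_stack_forward",
    "haar1d_stack_inverse",
    "subband_partition",
    "haar2d_matrix",
    "haar1d_matrix",
    "standard_subband_sizes",
]

_SQRT2 = np.sqrt(2.0)


def _check_side(n: int) -> int:
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(f"side length must be a power of two >= 2, got {n}")
    return int(np.log2(n))


def _resolve_depth(n: int, depth: int | None) -> int:
    max_depth = _check_side(n)
    if depth is None:
        return max_depth
    if not 1 <= depth <= max_depth:
        raise ValueError(f"depth must be in [1, {max_depth}] for side {n}, got {depth}")
    return depth


def haar2d_nonstandard_forward(block, depth: int | None = None):
    """Orthonormal non-standard 2-D Haar analysis of a square block.

    Returns ``(coefficients, SubbandMap)``.  ``depth=None`` decomposes to
    full depth (3 levels for an 8x8 block), at which point only a single
    scaling coefficient remains; for a constant block of value ``c`` that
    coefficient equals ``side * c``.
    """
    b = np.asarray(block, dtype=float)
    if b.ndim != 2 or b.shape[0] != b.shape[1]:
        raise ValueError("block must be 2-D and square")
    depth = _resolve_depth(b.shape[0], depth)
    out = b.copy()
    s = b.shape[0]
    for _ in range(depth):
        h = s // 2
        a = out[:s, :s]
        lo = (a[:, 0::2] + a[:, 1::2]) / _SQRT2
        hi = (a[:, 0::2] - a[:, 1::2]) / _SQRT2
        a[:, :h] = lo
        a[:, h:s] = hi
        lo = (a[0::2, :] + a[1::2, :]) / _SQRT2
        hi = (a[0::2, :] - a[1::2, :]) / _SQRT2
        a[:h, :] = lo
        a[h:s, :] = hi
        s = h
    return out, subband_partition(b.shape[0], 1, depth2d=depth)


def haar2d_nonstandard_inverse(coefficients, depth: int | None = None) -> np.ndarray:
    """Inverse of :func:`haar2d_nonstandard_forward`; exact reconstruction."""
    c = np.asarray(coefficients, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("coefficient array must be 2-D and square")
    depth = _resolve_depth(c.shape[0], depth)
    out = c.copy()
    n = c.shape[0]
    for lev in range(depth - 1, -1, -1):
        s = n >> lev
        h = s // 2
        a = out[:s, :s]
        lo, hi = a[:h, :].copy(), a[h:s, :].copy()
        a[0::2, :] = (lo + hi) / _SQRT2
        a[1::2, :] = (lo - hi) / _SQRT2
        lo, hi = a[:, :h].copy(), a[:, h:s].copy()
        a[:, 0::2] = (lo + hi) / _SQRT2
        a[:, 1::2] = (lo - hi) / _SQRT2
    return out


def haar2d_standard_forward(block) -> np.ndarray:
    """Standard-decomposition 2-D Haar: full 1-D transform of every row, then
    of every column.  Provided as the comparison baseline for subband sizes;
    orthonormal like the non-standard variant."""
    b = np.asarray(block, dtype=float)
    if b.ndim != 2 or b.shape[0] != b.shape[1]:
        raise ValueError("block must be 2-D and square")
    _check_side(b.shape[0])
    out = np.apply_along_axis(_haar1d_full, 1, b)
    out = np.apply_along_axis(_haar1d_full, 0, out)
    return out


def _haar1d_full(v: np.ndarray) -> np.ndarray:
    out = v.astype(float).copy()
    s = out.size
    while s > 1:
        h = s // 2
        lo = (out[0:s:2] + out[1:s:2]) / _SQRT2
        hi = (out[0:s:2] - out[1:s:2]) / _SQRT2
        out[:h] = lo
        out[h:s] = hi
        s = h
    return out


def _haar1d_full_inverse(v: np.ndarray) -> np.ndarray:
    out = v.astype(float).copy()
    n = out.size
    levels = int(np.log2(n))
    for lev in range(levels - 1, -1, -1):
        s = n >> lev
        h = s // 2
        lo, hi = out[:h].copy(), out[h:s].copy()
        out[0:s:2] = (lo + hi) / _SQRT2
        out[1:s:2] = (lo - hi) / _SQRT2
    return out


def haar1d_stack_forward(stack) -> np.ndarray:
    """Full-depth orthonormal 1-D Haar along the stack (last) axis.

    The stack depth must be a power of two; depth 1 is the identity.
    """
    x = np.asarray(stack, dtype=float)
    n = x.shape[-1]
    if n == 1:
        return x.copy()
    _check_side(n)
    return np.apply_along_axis(_haar1d_full, -1, x)


def haar1d_stack_inverse(coefficients) -> np.ndarray:
    """Exact inverse of :func:`haar1d_stack_forward`."""
    x = np.asarray(coefficients, dtype=float)
    n = x.shape[-1]
    if n == 1:
        return x.copy()
    _check_side(n)
    return np.apply_along_axis(_haar1d_full_inverse, -1, x)


# ---------------------------------------------------------------------------
# subband bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class SubbandMap:
    """Partition of a ``block x block x depth`` coefficient array into subbands.

    ``labels`` assigns every coefficient an integer subband id; id 0 is the
    protected scaling x scaling subband (lowest frequency in both the 2-D and
    the stack transform), which thresholding must never touch.  ``names``
    gives human-readable ids like ``"L2.HH|s1"`` (2-D level 2, diagonal
    orientation, coarsest stack detail scale).
    """

    labels: np.ndarray
    names: list
    sizes: np.ndarray
    protected: int = 0

    @property
    def n_subbands(self) -> int:
        return len(self.names)


def _labels2d(block_size: int, depth: int) -> tuple[np.ndarray, list]:
    """Per-pixel 2-D subband labels; 0 is the scaling band, then coarse->fine."""
    lab = np.zeros((block_size, block_size), dtype=np.intp)
    names: list[str] = []
    entries = []  # (level, orientation, mask) fine->coarse during construction
    s = block_size
    lev = 1
    while lev <= depth:
        h = s // 2
        for orient, (rs, cs) in (
            ("HL", (slice(0, h), slice(h, s))),      # detail along columns (x)
            ("LH", (slice(h, s), slice(0, h))),      # detail along rows (y)
            ("HH", (slice(h, s), slice(h, s))),
        ):
            entries.append((lev, orient, (rs, cs)))
        s = h
        lev += 1
    names.append(f"L{depth}.LL")
    # scaling region occupies the residual top-left corner
    # assign ids: scaling = 0, then deepest level first
    next_id = 1
    for level in range(depth, 0, -1):
        for elev, orient, (rs, cs) in entries:
            if elev == level:
                lab[rs, cs] = next_id
                names.append(f"L{elev}.{orient}")
                next_id += 1
    return lab, names


def _stack_scales(n_blocks: int) -> tuple[np.ndarray, list]:
    """Scale class of each position after a full-depth 1-D Haar of length n."""
    if n_blocks == 1:
        return np.zeros(1, dtype=np.intp), ["s0"]
    _check_side(n_blocks)
    levels = int(np.log2(n_blocks))
    scale = np.zeros(n_blocks, dtype=np.intp)
    names = ["s0"]
    for j in range(1, levels + 1):
        scale[1 << (j - 1) : 1 << j] = j
        names.append(f"s{j}")
    return scale, names


def subband_partition(
    block_size: int,
    n_blocks: int,
    depth2d: int | None = None,
    collapse_stack_scales: bool = False,
) -> SubbandMap:
    """Label every coefficient of a transformed group with its subband id.

    Subbands are the cross product of the 2-D bands (scaling + 3 orientations
    per level) with the stack scales of the 1-D Haar transform; with
    ``collapse_stack_scales=True`` the stack axis is pooled and subbands are
    the 2-D bands alone.  The scaling x scaling subband always has id 0 and
    is flagged protected.
    """
    depth2d = _resolve_depth(block_size, depth2d)
    lab2d, names2d = _labels2d(block_size, depth2d)
    scales, snames = _stack_scales(n_blocks)
    if collapse_stack_scales:
        labels = np.broadcast_to(lab2d[:, :, None], (block_size, block_size, n_blocks)).copy()
        names = list(names2d)
    else:
        k = len(snames)
        labels = lab2d[:, :, None] * k + scales[None, None, :]
        names = [f"{n2}|{sn}" for n2 in names2d for sn in snames]
    sizes = np.bincount(labels.ravel(), minlength=len(names))
    return SubbandMap(labels=labels, names=names, sizes=sizes, protected=0)


def standard_subband_sizes(block_size: int) -> np.ndarray:
    """Subband sizes of the full-depth *standard* 2-D decomposition.

    Subbands are all (row scale) x (column scale) combinations; used to check
    that the non-standard partition is never finer.
    """
    _check_side(block_size)
    levels = int(np.log2(block_size))
    scale_sizes = [1] + [1 << (j - 1) for j in range(1, levels + 1)]
    return np.array([a * b for a in scale_sizes for b in scale_sizes])


# ---------------------------------------------------------------------------
# matrix forms (used by the batched pipeline engine)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def haar2d_matrix(block_size: int, depth: int | None = None) -> np.ndarray:
    """The non-standard 2-D Haar analysis as an orthonormal matrix acting on
    row-major flattened blocks: ``coeffs.ravel() = M @ block.ravel()``."""
    n2 = block_size * block_size
    m = np.empty((n2, n2))
    for k in range(n2):
        e = np.zeros(n2)
        e[k] = 1.0
        m[:, k] = haar2d_nonstandard_forward(e.reshape(block_size, block_size), depth)[0].ravel()
    return m


@lru_cache(maxsize=None)
def haar1d_matrix(n: int) -> np.ndarray:
    """Full-depth 1-D Haar analysis as an orthonormal ``n x n`` matrix."""
    if n == 1:
        return np.ones((1, 1))
    _check_side(n)
    m = np.empty((n, n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = 1.0
        m[:, k] = _haar1d_full(e)
    return m
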