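"""Block matching with noise-adaptive similarity thresholds.

Two noisy blocks with identical ground truth differ only through their noise;
if the noise of the two blocks is pairwise uncorrelated the variance of the
pixel difference is ``sigma_eps^2 = 2 * sigma_eta^2`` (Bienaymé).  Blocks
whose ground truth is merely *similar* are admitted by an additive allowance
``Th_offset`` on that variance, giving the matching threshold

    level 1:  Th_BM = 2 * sigma_eta^2 + Th_offset
    level 2:  Th_BM = 2 * r * sigma_eta^2 + Th_offset

where the level-2 factor ``r`` (default 0.3) accounts for the noise variance
remaining in the basic estimate that matching runs on.  The recommended
offset for 2PM data is ``Th_offset = 900`` (in squared intensity units of the
domain being matched).

The block distance used throughout is the per-pixel mean squared difference,
so it is directly commensurable with ``Th_BM``, which is a variance of the
pixel difference.

Candidate positions are taken from a step lattice anchored at the image
origin, clipped to the search window, with the last row/column block position
appended so that image borders are always reachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import as_pixels

__all__ = [
    "BlockSpec",
    "MatchThreshold",
    "BlockGroup",
    "block_distance",
    "th_bm_level1",
    "th_bm_level2",
    "find_similar_blocks",
    "find_similar_blocks_pilot",
    "axis_lattice",
]


@dataclass(frozen=True)
class BlockSpec:
    """Geometry of the block-matching search.

    ``block_size`` pixels per side, ``step`` stride of the lattice,
    ``search_radius`` half-width of the search window, ``max_group`` the
    maximum (power-of-two) number of blocks per group.
    """

    block_size: int = 8
    step: int = 3
    search_radius: int = 19
    max_group: int = 16

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if not 1 <= self.step <= self.block_size:
            raise ValueError("step must satisfy 1 <= step <= block_size")
        if self.search_radius < 0:
            raise ValueError("search_radius must be non-negative")
        m = self.max_group
        if m < 1 or (m & (m - 1)) != 0:
            raise ValueError("max_group must be a power of two >= 1")


@dataclass(frozen=True)
class MatchThreshold:
    """Similarity threshold for one matching pass.

    ``sigma_eta_sq`` is the noise variance of the signal being matched (in
    squared units of that domain), ``th_offset`` the allowance for
    ground-truth dissimilarity, ``level`` selects the level-1 or level-2
    parameterization, and ``reduction`` the level-2 residual-noise fraction.
    ``fixed_value`` overrides the adaptive formula entirely (used by the
    original-BM3D baseline mode).
    """

    sigma_eta_sq: float = 1.0
    th_offset: float = 900.0
    level: int = 1
    reduction: float = 0.3
    fixed_value: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_eta_sq < 0 or self.th_offset < 0:
            raise ValueError("sigma_eta_sq and th_offset must be non-negative")
        if not 0 < self.reduction <= 1:
            raise ValueError("reduction must be in (0, 1]")
        if self.level not in (1, 2):
            raise ValueError("level must be 1 or 2")

    def value(self) -> float:
        if self.fixed_value is not None:
            return float(self.fixed_value)
        if self.level == 1:
            return th_bm_level1(self.sigma_eta_sq, self.th_offset)
        return th_bm_level2(self.sigma_eta_sq, self.th_offset, self.reduction)


@dataclass
class BlockGroup:
    """A stack of matched blocks with their source coordinates.

    ``coords[k]`` is the (row, col) top-left position of layer ``k`` of
    ``stack`` (shape ``block_size x block_size x n_blocks``); the reference
    block is always layer 0.  ``distances`` are per-pixel mean squared
    differences to the reference, non-decreasing.
    """

    coords: np.ndarray
    stack: np.ndarray
    distances: np.ndarray
    reference_index: int = 0

    @property
    def n_blocks(self) -> int:
        return self.stack.shape[-1]


def block_distance(b1, b2) -> float:
    """Per-pixel mean squared difference between two equally shaped blocks."""
    a = np.asarray(b1, dtype=float)
    b = np.asarray(b2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"block shapes differ: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def th_bm_level1(sigma_eta_sq: float, th_offset: float) -> float:
    """Level-1 matching threshold ``2*sigma_eta^2 + Th_offset``."""
    if sigma_eta_sq < 0 or th_offset < 0:
        raise ValueError("sigma_eta_sq and th_offset must be non-negative")
    return 2.0 * sigma_eta_sq + th_offset


def th_bm_level2(sigma_eta_sq: float, th_offset: float, reduction: float = 0.3) -> float:
    """Level-2 matching threshold ``2*reduction*sigma_eta^2 + Th_offset``."""
    if sigma_eta_sq < 0 or th_offset < 0:
        raise ValueError("sigma_eta_sq and th_offset must be non-negative")
    if not 0 < reduction <= 1:
        raise ValueError("reduction must be in (0, 1]")
    return 2.0 * reduction * sigma_eta_sq + th_offset


def axis_lattice(length: int, block_size: int, step: int) -> np.ndarray:
    """Block positions along one axis: the step lattice plus the last valid
    position, so borders are covered."""
    last = length - block_size
    if last < 0:
        raise ValueError(f"axis of length {length} cannot hold a block of {block_size}")
    ps = np.arange(0, last + 1, step)
    if ps[-1] != last:
        ps = np.append(ps, last)
    return ps


def _candidate_axis(ref: int, length: int, spec: BlockSpec) -> np.ndarray:
    lattice = axis_lattice(length, spec.block_size, spec.step)
    sel = lattice[np.abs(lattice - ref) <= spec.search_radius]
    if ref not in sel:
        sel = np.sort(np.append(sel, ref))
    return sel


def find_similar_blocks(image, ref, spec: BlockSpec, threshold: MatchThreshold) -> BlockGroup:
    """Group the blocks most similar to the reference block at ``ref``.

    All candidate positions on the (origin-anchored) step lattice inside the
    search window are scanned; candidates whose distance to the reference
    exceeds ``threshold.value()`` are discarded.  Survivors are ordered by
    ascending distance with ties broken in raster order, the reference block
    itself always first, and the group is truncated to the largest power of
    two that fits ``max_group``.
    """
    img = as_pixels(image)
    h, w = img.shape
    b = spec.block_size
    r0, c0 = int(ref[0]), int(ref[1])
    if not (0 <= r0 <= h - b and 0 <= c0 <= w - b):
        raise ValueError(f"reference block at {ref} does not fit inside image {img.shape}")
    th = threshold.value()

    rows = _candidate_axis(r0, h, spec)
    cols = _candidate_axis(c0, w, spec)
    refblk = img[r0 : r0 + b, c0 : c0 + b]
    kept: list[tuple[float, int, int, int]] = []  # (distance, raster, row, col)
    for rr in rows:
        for cc in cols:
            if rr == r0 and cc == c0:
                continue
            d = block_distance(refblk, img[rr : rr + b, cc : cc + b])
            if d <= th:
                kept.append((d, rr * w + cc, int(rr), int(cc)))
    kept.sort(key=lambda t: (t[0], t[1]))

    total = 1 + len(kept)
    n = min(total, spec.max_group)
    n = 1 << int(np.log2(n))
    coords = np.array([(r0, c0)] + [(t[2], t[3]) for t in kept[: n - 1]], dtype=np.intp)
    dists = np.array([0.0] + [t[0] for t in kept[: n - 1]])
    stack = np.stack([img[r : r + b, c : c + b] for r, c in coords], axis=-1)
    return BlockGroup(coords=coords, stack=stack, distances=dists)


def find_similar_blocks_pilot(
    noisy, pilot, ref, spec: BlockSpec, threshold: MatchThreshold
) -> tuple[BlockGroup, BlockGroup]:
    """Level-2 matching: decide similarity on the pilot, extract both stacks.

    The matching decisions (candidate selection, ordering, truncation) are
    computed on ``pilot`` only; the resulting coordinates extract one stack
    from ``noisy`` and one from ``pilot``.  Both groups share coordinates.
    """
    zn = as_pixels(noisy)
    zp = as_pixels(pilot)
    if zn.shape != zp.shape:
        raise ValueError(f"noisy and pilot shapes differ: {zn.shape} vs {zp.shape}")
    gp = find_similar_blocks(zp, ref, spec, threshold)
    b = spec.block_size
    stack_n = np.stack([zn[r : r + b, c : c + b] for r, c in gp.coords], axis=-1)
    gn = BlockGroup(coords=gp.coords.copy(), stack=stack_n, distances=gp.distances.copy())
    return gn, gp
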