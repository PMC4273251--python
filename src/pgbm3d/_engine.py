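"""Batched implementation of one BM3D level.

This module is the performance core behind :mod:`pgbm3d.pipeline`.  It
computes exactly what the per-group public operations in
:mod:`pgbm3d.block_matching` / :mod:`pgbm3d.collaborative_filtering` compute
-- same candidate lattice, same tie-breaking, same thresholds, same
aggregation weights -- but vectorized over all reference blocks at once:

* candidate sets are separable (per-axis lattice windows), so the distance
  tensor is built row-chunk by row-chunk with broadcasting;
* group selection is a stable argsort over the candidate axis (candidates
  are enumerated in raster order, which realizes the distance-then-raster
  tie-break; the reference gets a -inf key so it is always member 0);
* groups are batched by their power-of-two size and pushed through the
  3-D Haar transform as matrix products;
* per-subband statistics use a precomputed label permutation and
  ``np.add.reduceat``;
* aggregation scatters through ``np.bincount``.

The equivalence with the composition of the public operations is asserted by
the test suite on small images.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .block_matching import BlockSpec, axis_lattice
from .collaborative_filtering import WIENER_ENERGY_FLOOR
from .transforms import haar1d_matrix, haar2d_matrix, subband_partition

__all__ = ["run_level"]


def _axis_windows(refs: np.ndarray, lattice: np.ndarray, radius: int):
    """Candidate positions (valid-first, increasing) per reference position."""
    mask = np.abs(lattice[None, :] - refs[:, None]) <= radius
    kmax = int(mask.sum(axis=1).max())
    order = np.argsort(~mask, axis=1, kind="stable")[:, :kmax]
    cand = lattice[order]
    valid = np.take_along_axis(mask, order, axis=1)[:, :kmax]
    return cand, valid


@lru_cache(maxsize=None)
def _subband_tables(block_size: int, n_blocks: int, depth2d, collapse: bool):
    """Permutation/segment tables for per-subband statistics on (n, b*b) arrays."""
    smap = subband_partition(block_size, n_blocks, depth2d=depth2d,
                             collapse_stack_scales=collapse)
    # engine coefficient layout: axis 0 = stack position, axis 1 = flat 2-D coeff
    labels = np.moveaxis(smap.labels, -1, 0).reshape(n_blocks, -1).ravel()
    perm = np.argsort(labels, kind="stable")
    sorted_labels = labels[perm]
    seg_starts = np.searchsorted(sorted_labels, np.arange(smap.n_subbands))
    counts = smap.sizes.astype(float)
    label_of_perm = sorted_labels
    return smap, perm, np.argsort(perm), seg_starts, counts, label_of_perm


def _hard_threshold_batch(coeffs, tables, sigma, mode, lam):
    """Vectorized per-subband hard thresholding of (m, n*b*b) coefficients."""
    smap, perm, inv_perm, seg_starts, counts, label_of_perm = tables
    cp = coeffs[:, perm]
    n_bands = smap.n_subbands
    if mode == "bayes":
        if sigma > 0:
            sums = np.add.reduceat(cp**2, seg_starts, axis=1)
            mean_sq = sums / counts[None, :]
            sigma_y = np.sqrt(np.maximum(mean_sq - sigma**2, 0.0))
            th = np.where(sigma_y > 0, sigma**2 / np.maximum(sigma_y, 1e-300), np.inf)
        else:
            th = np.zeros((coeffs.shape[0], n_bands))
    elif mode == "fixed":
        th = np.full((coeffs.shape[0], n_bands), lam * sigma)
    else:
        raise ValueError(f"unknown hard-threshold mode {mode!r}")
    th[:, smap.protected] = 0.0
    th_coeff = th[:, label_of_perm]
    keep = ~(np.abs(cp) < th_coeff)
    out = np.where(keep, cp, 0.0)[:, inv_perm]
    retained = keep.sum(axis=1)
    return out, retained


def _match(match_img: np.ndarray, spec: BlockSpec, th: float):
    """Block matching for every reference on the lattice.

    Returns (member_flat_idx (Nr, Nc, max_group) indices into the patch grid,
    group_size (Nr, Nc), lattice rows, lattice cols, patch-grid width).
    """
    h, w = match_img.shape
    b = spec.block_size
    rows = axis_lattice(h, b, spec.step)
    cols = axis_lattice(w, b, spec.step)
    wp = w - b + 1

    patches = sliding_window_view(match_img, (b, b)).reshape(h - b + 1, wp, b * b)
    cand_r, valid_r = _axis_windows(rows, rows, spec.search_radius)
    cand_c, valid_c = _axis_windows(cols, cols, spec.search_radius)
    kr, kc = cand_r.shape[1], cand_c.shape[1]
    self_r = np.argmax(cand_r == rows[:, None], axis=1)
    self_c = np.argmax(cand_c == cols[:, None], axis=1)

    nr, nc = rows.size, cols.size
    dist = np.empty((nr, nc, kr * kc))
    inv_b2 = 1.0 / (b * b)
    for a in range(nr):
        ref_p = patches[rows[a], cols]                       # (nc, b*b)
        cp = patches[cand_r[a][:, None, None], cand_c[None, :, :]]  # (kr, nc, kc, b*b)
        d = cp - ref_p[None, :, None, :]
        d = np.einsum("ibjk,ibjk->ibj", d, d) * inv_b2       # (kr, nc, kc)
        d = np.moveaxis(d, 0, 1).reshape(nc, kr * kc)
        invalid = ~(valid_r[a][:, None, None] & valid_c[None, :, :]).transpose(1, 0, 2)
        dist[a] = np.where(invalid.reshape(nc, kr * kc), np.inf, d)
    # force the reference first in every group
    flat_self = self_r[:, None] * kc + self_c[None, :]
    np.put_along_axis(
        dist.reshape(nr * nc, kr * kc),
        flat_self.reshape(-1, 1),
        -np.inf,
        axis=1,
    )
    count = (dist <= th).sum(axis=-1)
    gsize = np.minimum(count, spec.max_group)
    gsize = 1 << np.floor(np.log2(gsize)).astype(np.intp)
    order = np.argsort(dist, axis=-1, kind="stable")[..., : spec.max_group]
    top_i, top_j = order // kc, order % kc
    member_r = cand_r[np.arange(nr)[:, None, None], top_i]
    member_c = cand_c[np.arange(nc)[None, :, None], top_j]
    member_idx = member_r * wp + member_c
    return member_idx, gsize, rows, cols, wp


def run_level(
    noisy: np.ndarray,
    match_on: np.ndarray,
    spec: BlockSpec,
    threshold_value: float,
    sigma: float,
    *,
    stage: str,
    hard_mode: str = "bayes",
    lam: float = 2.7,
    pilot: np.ndarray | None = None,
    depth2d: int | None = None,
    collapse_stack_scales: bool = False,
) -> np.ndarray:
    """Run one full BM3D level and return the aggregated estimate.

    ``stage='hard'`` groups and hard-thresholds stacks from ``noisy``
    (matching on ``match_on``, normally the same image).  ``stage='wiener'``
    matches on ``match_on`` (the basic estimate), extracts stacks from both
    ``noisy`` and ``pilot`` and applies empirical Wiener shrinkage.
    """
    noisy = np.asarray(noisy, dtype=np.float64)
    match_img = np.asarray(match_on, dtype=np.float64)
    if match_img.shape != noisy.shape:
        raise ValueError("matching image must share the noisy image's shape")
    if stage == "wiener":
        if pilot is None:
            raise ValueError("wiener stage requires a pilot image")
        pilot = np.asarray(pilot, dtype=np.float64)
        if pilot.shape != noisy.shape:
            raise ValueError("pilot must share the noisy image's shape")
    elif stage != "hard":
        raise ValueError(f"unknown stage {stage!r}")

    h, w = noisy.shape
    b = spec.block_size
    if h < b or w < b:
        raise ValueError(f"image {noisy.shape} is smaller than one {b}x{b} block")

    member_idx, gsize, rows, cols, wp = _match(match_img, spec, threshold_value)
    member_flat = member_idx.reshape(-1, spec.max_group)
    gflat = gsize.ravel()

    patches_n = sliding_window_view(noisy, (b, b)).reshape(-1, b * b)
    patches_p = (
        sliding_window_view(pilot, (b, b)).reshape(-1, b * b) if stage == "wiener" else None
    )

    m2 = haar2d_matrix(b, depth2d)
    num = np.zeros(h * w)
    den = np.zeros(h * w)
    pix_offsets = (np.arange(b)[:, None] * w + np.arange(b)[None, :]).ravel()

    for n in np.unique(gflat):
        sel = np.nonzero(gflat == n)[0]
        idx = member_flat[sel, :n]                           # (m, n)
        hn = haar1d_matrix(int(n))
        x = patches_n[idx]                                   # (m, n, b*b)
        c = np.einsum("ij,mjk->mik", hn, x @ m2.T)
        mshape = c.shape
        if stage == "hard":
            tables = _subband_tables(b, int(n), depth2d, collapse_stack_scales)
            cf, retained = _hard_threshold_batch(
                c.reshape(len(sel), -1), tables, sigma, hard_mode, lam
            )
            cf = cf.reshape(mshape)
            weight = 1.0 / np.maximum(retained, 1.0)
        else:
            p = np.einsum("ij,mjk->mik", hn, patches_p[idx] @ m2.T)
            p2 = p**2
            denom = p2 + sigma**2
            wien = np.divide(p2, denom, out=np.zeros_like(p2), where=denom > 0)
            cf = wien * c
            energy = np.einsum("mjk,mjk->m", wien, wien)
            weight = 1.0 / np.maximum(energy, WIENER_ENERGY_FLOOR)
        blocks = np.einsum("ij,mjk->mik", hn.T, cf) @ m2     # (m, n, b*b)
        cy, cx = idx // wp, idx % wp
        pix = (cy * w + cx)[:, :, None] + pix_offsets[None, None, :]
        wvals = np.broadcast_to(weight[:, None, None], blocks.shape)
        num += np.bincount(pix.ravel(), weights=(wvals * blocks).ravel(), minlength=h * w)
        den += np.bincount(pix.ravel(), weights=wvals.ravel(), minlength=h * w)

    covered = den > 0
    out = np.where(covered, num / np.where(covered, den, 1.0), noisy.ravel())
    return out.reshape(h, w)
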