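"""Texture-matrix builders (GLCM, GLRLM, GLSZM, NGTDM) for 2D and 3D ROIs.

All builders operate on an integer level grid (1..n_levels inside the mask)
and count only voxels/pairs that lie fully inside the mask. Distance is
fixed at 1 voxel. Direction sets:

* 3D: the 13 unique offsets of the 26-neighborhood (one of each +/- pair);
* 2D: the 4 unique offsets of the 8-neighborhood.

GLCMs are symmetric (each pair counted in both orders) and normalized per
direction. Run-length runs are truncated at the mask boundary. GLSZM zones
use 26-connectivity (3D) / 8-connectivity (2D).
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "unique_directions",
    "glcm_matrices",
    "glrlm_matrices",
    "glszm_matrix",
    "ngtdm_table",
]


def unique_directions(ndim: int) -> list[tuple[int, ...]]:
    """Half of the (3^ndim - 1) neighbor offsets: the lexicographically
    positive representative of each +/- pair. 13 offsets in 3D, 4 in 2D."""
    dirs = []
    for off in product((-1, 0, 1), repeat=ndim):
        if off == (0,) * ndim:
            continue
        if off > tuple(-o for o in off):
            dirs.append(off)
    return dirs


def _shift_slices(shape, offset):
    """Slices (src, dst) so that grid[dst] = grid[src] shifted by +offset."""
    src, dst = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def glcm_matrices(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Symmetric, normalized distance-1 co-occurrence matrices, one per
    unique direction. Directions with no valid in-mask pair are skipped.

    Raises ValueError if no direction has any valid pair.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    mats = []
    for off in unique_directions(levels.ndim):
        src, dst = _shift_slices(levels.shape, off)
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        a = levels[src][valid] - 1
        b = levels[dst][valid] - 1
        counts = np.zeros((n_levels, n_levels), dtype=float)
        np.add.at(counts, (a, b), 1.0)
        counts = counts + counts.T
        mats.append(counts / counts.sum())
    if not mats:
        raise ValueError("GLCM: no in-mask voxel pair in any direction")
    return mats


def glrlm_matrices(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Run-length count matrices R(level, run_length), one per unique
    direction. Runs are maximal straight segments of equal level fully
    inside the mask; they are truncated at mask/grid boundaries.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    shape = levels.shape
    max_len = int(np.ceil(np.sqrt(sum((n - 1) ** 2 for n in shape)))) + 1
    mats = []
    for off in unique_directions(levels.ndim):
        # A voxel starts a run iff its predecessor along -off is outside the
        # mask/grid or has a different level.
        src, dst = _shift_slices(shape, off)
        cont = np.zeros(shape, dtype=bool)  # has an in-mask same-level predecessor
        cont[dst] = mask[dst] & mask[src] & (levels[dst] == levels[src])
        starts = mask & ~cont
        coords = np.argwhere(starts)
        run_levels = levels[starts]
        run_lengths = np.ones(len(coords), dtype=int)
        cur = coords.copy()
        alive = np.arange(len(coords))
        step = np.asarray(off)
        while alive.size:
            nxt = cur + step
            inside = np.all((nxt >= 0) & (nxt < np.asarray(shape)), axis=1)
            ok = inside.copy()
            if inside.any():
                idx = tuple(nxt[inside].T)
                ok[inside] = mask[idx] & (levels[idx] == run_levels[alive[inside]])
            run_lengths[alive[ok]] += 1
            alive = alive[ok]
            cur = nxt[ok]
        counts = np.zeros((n_levels, max_len), dtype=float)
        np.add.at(counts, (run_levels - 1, run_lengths - 1), 1.0)
        mats.append(counts)
    return mats


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone count matrix Z(level, zone_size): connected components of equal
    level, 26-connectivity in 3D 8-connectivity in 2D."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    structure = np.ones((3,) * levels.ndim, dtype=bool)
    counts = np.zeros((n_levels, n_vox), dtype=float)
    present = np.unique(levels[mask])
    for lev in present:
        lab, n_lab = ndi.label(mask & (levels == lev), structure=structure)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(counts, (np.full(n_lab, lev - 1), sizes - 1), 1.0)
    return counts


def ngtdm_table(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Neighbor gray tone difference table.

    Returns ``(n_i, p_i, s_i)`` over levels 1..n_levels where n_i counts
    in-mask voxels of level i with at least one in-mask neighbor (26/8
    neighborhood), p_i = n_i / sum(n), and
    s_i = sum over those voxels of |i - mean(in-mask neighbors)|.

    Raises ValueError if no voxel has an in-mask neighbor.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    kernel = np.ones((3,) * levels.ndim, dtype=float)
    kernel[(1,) * levels.ndim] = 0.0
    mfloat = mask.astype(float)
    nbr_count = ndi.convolve(mfloat, kernel, mode="constant", cval=0.0)
    nbr_sum = ndi.convolve(levels * mfloat, kernel, mode="constant", cval=0.0)
    valid = mask & (nbr_count > 0.5)
    if not valid.any():
        raise ValueError("NGTDM: no in-mask voxel has an in-mask neighbor")
    nbr_mean = nbr_sum[valid] / nbr_count[valid]
    lev = levels[valid]
    dev = np.abs(lev - nbr_mean)
    n_i = np.zeros(n_levels, dtype=float)
    s_i = np.zeros(n_levels, dtype=float)
    np.add.at(n_i, lev - 1, 1.0)
    np.add.at(s_i, lev - 1, dev)
    p_i = n_i / n_i.sum()
    return n_i, p_i, s_i
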