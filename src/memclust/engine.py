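"""Numba kernels: neighbour counting and the per-frame simulation loop.

Everything here is an implementation detail behind :mod:`memclust.geometry`
and :mod:`memclust.simulate`.  Two counting routes are provided — a
cell-list accelerator (bin width >= R) and an exact all-pairs sweep —
which agree integer-for-integer, including the tie rule that a pair at
distance exactly R is counted.

The simulation kernel keeps the per-molecule neighbour counts up to date
incrementally: each frame, only pairs involving molecules that actually
moved are re-examined (removed at the old position, re-inserted at the
new one).  Once most molecules are frozen inside dense clusters this
avoids re-scanning the quadratically many intra-cluster pairs; when most
molecules are mobile the kernel recounts from scratch, whichever is
cheaper.  The random stream is numpy's MT19937 seeded with the motion
seed, drawn in molecule-index order (one uniform per fixed-length step,
two per Gaussian step), which makes the kernel reproducible draw-for-draw
by the pure-Python reference stepper.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Profile family codes shared with memclust.motion.
PROFILE_LINEAR = 0
PROFILE_FLOOR = 1
PROFILE_TENT = 2
PROFILE_QUAD = 3

# Minimum number of bins per axis for the cell list to resolve the
# minimum image with only adjacent-cell lookups.
MIN_GRID = 4

# Bins are never narrower than 1 nm.
MIN_BIN = 1.0


def grid_shape(box_w: float, box_h: float, R: float) -> tuple[int, int]:
    """Cell-grid dimensions for radius R (bin width >= max(R, 1 nm))."""
    b = max(R, MIN_BIN)
    return max(1, int(box_w // b)), max(1, int(box_h // b))


@njit(cache=True, fastmath=True)
def _brute_counts(x, y, box_w, box_h, R, counts):
    n = x.shape[0]
    for i in range(n):
        counts[i] = 0
    hw = box_w / 2.0
    hh = box_h / 2.0
    R2 = R * R
    for i in range(n):
        xi = x[i]
        yi = y[i]
        for j in range(i + 1, n):
            dx = x[j] - xi
            if dx > hw:
                dx -= box_w
            elif dx < -hw:
                dx += box_w
            dy = y[j] - yi
            if dy > hh:
                dy -= box_h
            elif dy < -hh:
                dy += box_h
            if dx * dx + dy * dy <= R2:
                counts[i] += 1
                counts[j] += 1


def brute_counts(x, y, box_w, box_h, R):
    counts = np.zeros(x.shape[0], dtype=np.int64)
    _brute_counts(x, y, box_w, box_h, R, counts)
    return counts


@njit(cache=True, fastmath=True)
def _bin_points(x, y, box_w, box_h, ncx, ncy, cell_id, cell_cursor, cell_start, order):
    """Counting-sort molecules into grid cells (O(n + n_cells))."""
    n = x.shape[0]
    cw = box_w / ncx
    ch = box_h / ncy
    ncells = ncx * ncy
    for i in range(n):
        cx = int(x[i] / cw)
        if cx >= ncx:
            cx = ncx - 1
        cy = int(y[i] / ch)
        if cy >= ncy:
            cy = ncy - 1
        cell_id[i] = cy * ncx + cx
    for c in range(ncells):
        cell_cursor[c] = 0
    for i in range(n):
        cell_cursor[cell_id[i]] += 1
    s = 0
    for c in range(ncells):
        cell_start[c] = s
        s += cell_cursor[c]
    cell_start[ncells] = s
    for c in range(ncells):
        cell_cursor[c] = 0
    for i in range(n):
        c = cell_id[i]
        order[cell_start[c] + cell_cursor[c]] = i
        cell_cursor[c] += 1


@njit(cache=True, fastmath=True)
def _cell_counts(x, y, box_w, box_h, R, ncx, ncy,
                 cell_id, cell_cursor, cell_start, order, counts):
    """Full neighbour count via a half-neighbourhood cell sweep.

    Each unordered pair is examined once: within-cell pairs (j > i) plus
    the four offsets (1,0), (-1,1), (0,1), (1,1); wrap shifts are
    resolved per cell pair, so no per-pair modulo is needed.
    """
    n = x.shape[0]
    _bin_points(x, y, box_w, box_h, ncx, ncy, cell_id, cell_cursor, cell_start, order)
    for i in range(n):
        counts[i] = 0
    R2 = R * R
    for cyc in range(ncy):
        for cxc in range(ncx):
            c = cyc * ncx + cxc
            a0 = cell_start[c]
            a1 = cell_start[c + 1]
            for ii in range(a0, a1):
                i = order[ii]
                xi = x[i]
                yi = y[i]
                for jj in range(ii + 1, a1):
                    j = order[jj]
                    dx = x[j] - xi
                    dy = y[j] - yi
                    if dx * dx + dy * dy <= R2:
                        counts[i] += 1
                        counts[j] += 1
            for k in range(4):
                if k == 0:
                    ox, oy = 1, 0
                elif k == 1:
                    ox, oy = -1, 1
                elif k == 2:
                    ox, oy = 0, 1
                else:
                    ox, oy = 1, 1
                nx_ = cxc + ox
                ny_ = cyc + oy
                sx = 0.0
                sy = 0.0
                if nx_ < 0:
                    nx_ += ncx
                    sx = -box_w
                elif nx_ >= ncx:
                    nx_ -= ncx
                    sx = box_w
                if ny_ >= ncy:
                    ny_ -= ncy
                    sy = box_h
                d = ny_ * ncx + nx_
                b0 = cell_start[d]
                b1 = cell_start[d + 1]
                for ii in range(a0, a1):
                    i = order[ii]
                    xi = x[i] - sx
                    yi = y[i] - sy
                    for jj in range(b0, b1):
                        j = order[jj]
                        dx = x[j] - xi
                        dy = y[j] - yi
                        if dx * dx + dy * dy <= R2:
                            counts[i] += 1
                            counts[j] += 1


def cell_counts(x, y, box_w, box_h, R):
    ncx, ncy = grid_shape(box_w, box_h, R)
    n = x.shape[0]
    ncells = ncx * ncy
    cell_id = np.empty(n, np.int64)
    cell_cursor = np.empty(ncells, np.int64)
    cell_start = np.empty(ncells + 1, np.int64)
    order = np.empty(n, np.int64)
    counts = np.empty(n, np.int64)
    _cell_counts(x, y, box_w, box_h, R, ncx, ncy,
                 cell_id, cell_cursor, cell_start, order, counts)
    return counts


@njit(cache=True, fastmath=True, inline="always")
def _pair_update(i, x, y, box_w, box_h, R2, ncx, ncy,
                 cell_cursor, cell_start, order, counts, mover, sign):
    """Add/remove all pairs involving molecule ``i`` from ``counts``.

    Scans the full 3x3 cell neighbourhood of i's current position.
    Mover-mover pairs are applied only from the higher index so that
    each pair is touched exactly once per phase.
    """
    cw = box_w / ncx
    ch = box_h / ncy
    xi0 = x[i]
    yi0 = y[i]
    cx = int(xi0 / cw)
    if cx >= ncx:
        cx = ncx - 1
    cy = int(yi0 / ch)
    if cy >= ncy:
        cy = ncy - 1
    for oy in range(-1, 2):
        ny_ = cy + oy
        sy = 0.0
        if ny_ < 0:
            ny_ += ncy
            sy = -box_h
        elif ny_ >= ncy:
            ny_ -= ncy
            sy = box_h
        for ox in range(-1, 2):
            nx_ = cx + ox
            sx = 0.0
            if nx_ < 0:
                nx_ += ncx
                sx = -box_w
            elif nx_ >= ncx:
                nx_ -= ncx
                sx = box_w
            d = ny_ * ncx + nx_
            b0 = cell_start[d]
            b1 = cell_start[d + 1]
            xi = xi0 - sx
            yi = yi0 - sy
            for jj in range(b0, b1):
                j = order[jj]
                if j == i or (mover[j] and j < i):
                    continue
                dx = x[j] - xi
                dy = y[j] - yi
                if dx * dx + dy * dy <= R2:
                    counts[i] += sign
                    counts[j] += sign


@njit(cache=True, fastmath=True)
def run_kernel(x, y, n_frames, box_w, box_h, R, dt,
               profile_id, d_max, d_min, l_target, l_anchor,
               gaussian_mode, mesh_spacing, motion_seed,
               record_stride, frames_out, mean_l, early_stop):
    """Advance the pattern ``n_frames`` frames in place.

    Synchronous update: per frame all L values are computed from the
    pre-move snapshot, rates follow the displacement profile, every
    mobile molecule takes its step, and mesh reflection / toroidal wrap
    are applied.  ``mean_l`` (length n_frames + 1) receives the mean L
    of the pattern at every frame time, measured before that frame's
    moves; thinned snapshots go to ``frames_out`` every
    ``record_stride`` frames (0 disables recording).

    If the profile freezes molecules at the target (d_min == 0, linear
    or quadratic family) and every molecule is frozen, the pattern can
    never change again; with ``early_stop`` the remaining frames are
    filled with the frozen state.
    """
    np.random.seed(motion_seed)
    n = x.shape[0]
    bw = max(R, MIN_BIN)
    ncx = max(1, int(box_w // bw))
    ncy = max(1, int(box_h // bw))
    use_cells = ncx >= MIN_GRID and ncy >= MIN_GRID
    ncells = ncx * ncy
    cell_id = np.empty(n, np.int64)
    cell_cursor = np.empty(max(ncells, 1), np.int64)
    cell_start = np.empty(max(ncells, 1) + 1, np.int64)
    order = np.empty(n, np.int64)
    counts = np.empty(n, np.int64)
    rate = np.empty(n, np.float64)
    mover = np.zeros(n, np.bool_)
    A = box_w * box_h
    lcoef = A / (math.pi * (n - 1)) if n > 1 else 0.0
    inv_span = 1.0 / (l_target - l_anchor)
    two_pi = 2.0 * math.pi
    can_freeze = (profile_id == PROFILE_LINEAR or profile_id == PROFILE_QUAD)
    # Incremental updates pay off when the mobile fraction is modest.
    incr_threshold = (n * 11) // 20
    R2 = R * R
    counts_valid = False
    rec = 0
    n_store = frames_out.shape[0]
    for t in range(n_frames + 1):
        if not counts_valid:
            if use_cells:
                _cell_counts(x, y, box_w, box_h, R, ncx, ncy,
                             cell_id, cell_cursor, cell_start, order, counts)
            else:
                _brute_counts(x, y, box_w, box_h, R, counts)
            counts_valid = True
        msum = 0.0
        n_mov = 0
        for i in range(n):
            L = math.sqrt(lcoef * counts[i])
            msum += L
            if profile_id == PROFILE_TENT:
                u = abs(l_target - L) * inv_span
                if u > 1.0:
                    u = 1.0
                r = d_max * u
            else:
                u = (l_target - L) * inv_span
                if u < 0.0:
                    u = 0.0
                elif u > 1.0:
                    u = 1.0
                if profile_id == PROFILE_QUAD:
                    r = d_max * u * u
                else:
                    r = d_max * u
                if profile_id == PROFILE_FLOOR and r < d_min:
                    r = d_min
            rate[i] = r
            is_mov = r > 0.0
            mover[i] = is_mov
            if is_mov:
                n_mov += 1
        mean_l[t] = msum / n if n > 0 else 0.0
        if record_stride > 0 and t < n_frames and t % record_stride == 0 and rec < n_store:
            for i in range(n):
                frames_out[rec, i, 0] = x[i]
                frames_out[rec, i, 1] = y[i]
            rec += 1
        if t == n_frames:
            break
        if n_mov == 0 and can_freeze and early_stop:
            for tt in range(t + 1, n_frames + 1):
                mean_l[tt] = mean_l[t]
            if record_stride > 0:
                while rec < n_store:
                    for i in range(n):
                        frames_out[rec, i, 0] = x[i]
                        frames_out[rec, i, 1] = y[i]
                    rec += 1
            break
        incremental = use_cells and 0 < n_mov <= incr_threshold
        if incremental:
            # Phase 1: remove pairs involving movers at old positions.
            for i in range(n):
                if mover[i]:
                    _pair_update(i, x, y, box_w, box_h, R2, ncx, ncy,
                                 cell_cursor, cell_start, order, counts, mover, -1)
        # Move (draws in molecule-index order).
        for i in range(n):
            if not mover[i]:
                continue
            step = rate[i] * dt
            if gaussian_mode:
                u1 = np.random.random()
                u2 = np.random.random()
                rad = (step / math.sqrt(2.0)) * math.sqrt(-2.0 * math.log(1.0 - u1))
                ang = two_pi * u2
            else:
                rad = step
                ang = two_pi * np.random.random()
            nx_ = x[i] + rad * math.cos(ang)
            ny_ = y[i] + rad * math.sin(ang)
            if mesh_spacing > 0.0:
                period = 2.0 * mesh_spacing
                lo = math.floor(x[i] / mesh_spacing) * mesh_spacing
                v = (nx_ - lo) % period
                if v > mesh_spacing:
                    v = period - v
                nx_ = lo + v
                lo = math.floor(y[i] / mesh_spacing) * mesh_spacing
                v = (ny_ - lo) % period
                if v > mesh_spacing:
                    v = period - v
                ny_ = lo + v
            else:
                nx_ = nx_ % box_w
                ny_ = ny_ % box_h
            x[i] = nx_
            y[i] = ny_
        if incremental:
            # Phase 2: re-insert movers at their new positions.
            _bin_points(x, y, box_w, box_h, ncx, ncy,
                        cell_id, cell_cursor, cell_start, order)
            for i in range(n):
                if mover[i]:
                    _pair_update(i, x, y, box_w, box_h, R2, ncx, ncy,
                                 cell_cursor, cell_start, order, counts, mover, 1)
        else:
            counts_valid = False
    return rec
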