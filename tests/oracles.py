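"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain Python loops over voxels,
lines and score pairs — no shared code with the package's vectorized paths.
"""

from __future__ import annotations

import numpy as np

from radstage.grids import ROIMask
from radstage.texture import DIRECTIONS, GreyVolume


def grey_from_slices(arr, L: int) -> GreyVolume:
    """Wrap a 2D slice (or 3D stack) of integer levels as a GreyVolume."""
    arr = np.asarray(arr, dtype=np.int32)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    mask = ROIMask(np.ones_like(arr, dtype=bool))
    return GreyVolume(arr, L=L, mask=mask)


def brute_glcm_counts(levels: np.ndarray, mask: np.ndarray, L: int,
                      direction: str, offset: int) -> np.ndarray:
    """Symmetrized pair counts by explicit enumeration of ordered pairs."""
    di, dj = DIRECTIONS[direction]
    oi, oj = di * offset, dj * offset
    nx, ny, nz = levels.shape
    counts = np.zeros((L, L), dtype=float)
    for z in range(nz):
        for x in range(nx):
            for y in range(ny):
                if not mask[x, y, z]:
                    continue
                xb, yb = x + oi, y + oj
                if 0 <= xb < nx and 0 <= yb < ny and mask[xb, yb, z]:
                    a, b = levels[x, y, z], levels[xb, yb, z]
                    counts[a, b] += 1
                    counts[b, a] += 1
    return counts


def brute_rlm_counts(levels: np.ndarray, mask: np.ndarray,
                     direction: str, step: int) -> dict[tuple[int, int], int]:
    """Run counts {(grey, length): n} by walking every scan line explicitly.

    Lines run along the direction with stride ``step``; the scan lattice is
    anchored at slice index 0 (phase 0 of the stride).
    """
    di, dj = DIRECTIONS[direction]
    sx, sy = di * step, dj * step
    nx, ny, nz = levels.shape

    def on_lattice(x: int, y: int) -> bool:
        if (di, dj) == (0, 1):
            return y % step == 0
        return x % step == 0

    runs: dict[tuple[int, int], int] = {}
    for z in range(nz):
        for x0 in range(nx):
            for y0 in range(ny):
                if not on_lattice(x0, y0):
                    continue
                px, py = x0 - sx, y0 - sy
                if 0 <= px < nx and 0 <= py < ny:
                    continue  # not a line start
                x, y = x0, y0
                cur_grey, cur_len = None, 0
                while 0 <= x < nx and 0 <= y < ny:
                    if mask[x, y, z]:
                        g = int(levels[x, y, z])
                        if g == cur_grey:
                            cur_len += 1
                        else:
                            if cur_len:
                                runs[(cur_grey, cur_len)] = runs.get(
                                    (cur_grey, cur_len), 0) + 1
                            cur_grey, cur_len = g, 1
                    else:
                        if cur_len:
                            runs[(cur_grey, cur_len)] = runs.get(
                                (cur_grey, cur_len), 0) + 1
                        cur_grey, cur_len = None, 0
                    x, y = x + sx, y + sy
                if cur_len:
                    runs[(cur_grey, cur_len)] = runs.get(
                        (cur_grey, cur_len), 0) + 1
    return runs


def brute_auc(scores, labels) -> float:
    """Mann-Whitney AUC by pair counting with half credit for ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
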