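"""Independent brute-force oracles used to pin the fast implementations.

Everything here is deliberately naive — exhaustive double loops, explicit
sums, full enumeration — and shares no code with the package internals it
checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from contourvar import LabelVolume


# -- geometry ---------------------------------------------------------------

def brute_nearest_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exhaustive O(|X|·|Y|) nearest-point distances from each x to Y."""
    diff = x[:, None, :] - y[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)


def brute_directed_hd(x: np.ndarray, y: np.ndarray) -> float:
    return float(brute_nearest_distances(x, y).max())


def brute_percentile(values: np.ndarray, q: float) -> float:
    """Percentile with linear interpolation between closest order statistics."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 1:
        return float(v[0])
    pos = (q / 100.0) * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def brute_boundary_count(voxels: np.ndarray) -> int:
    """Neighbour-scan boundary voxel count (6-connectivity, explicit loops)."""
    count = 0
    nx, ny, nz = voxels.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not voxels[i, j, k]:
                    continue
                for di, dj, dk in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                    a, b, c = i + di, j + dj, k + dk
                    if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) or not voxels[a, b, c]:
                        count += 1
                        break
    return count


# -- statistics -------------------------------------------------------------

def anova_icc_2_1(data: np.ndarray) -> float:
    """ICC(2,1) from explicit elementwise sums of squares (no vectorized reuse)."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = sum(data[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(data[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(data[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sst = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def enumerate_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating every n-subset of the pooled
    sample, using the symmetric-deviation tail P(|W - E W| >= |w_obs - E W|)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    # midranks by hand
    sorted_vals = pooled[order]
    i = 0
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n = len(x)
    w_obs = ranks[:n].sum()
    mean_w = n * ranks.mean()
    dev = abs(w_obs - mean_w)
    hits = 0
    total = 0
    for subset in combinations(range(len(pooled)), n):
        w = sum(ranks[i] for i in subset)
        total += 1
        if abs(w - mean_w) >= dev - 1e-9:
            hits += 1
    return hits / total


# -- mask construction ------------------------------------------------------

def random_mask_pair(
    rng: np.random.Generator,
    shape=(12, 12, 8),
    spacing=(1.0, 1.0, 3.0),
) -> tuple[LabelVolume, LabelVolume]:
    """Two random non-empty blobby masks on a shared anisotropic grid."""
    def blob() -> np.ndarray:
        vox = np.zeros(shape, dtype=bool)
        n_seeds = rng.integers(1, 4)
        centers = rng.uniform(0, np.asarray(shape), size=(n_seeds, 3))
        radii = rng.uniform(1.5, 4.0, size=n_seeds)
        idx = np.indices(shape).reshape(3, -1).T
        for c, r in zip(centers, radii):
            vox.reshape(-1)[((idx - c) ** 2).sum(axis=1) <= r**2] = True
        if not vox.any():
            vox[tuple(rng.integers(0, s) for s in shape)] = True
        return vox

    return (LabelVolume(blob(), spacing), LabelVolume(blob(), spacing))
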