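"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_border(occ: np.ndarray) -> set:
    """Set voxels with any 6-neighbor unset or outside, by explicit loop."""
    out = set()
    n, r, c = occ.shape
    for i, j, k in np.argwhere(occ):
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ii, jj, kk = i + di, j + dj, k + dk
            if not (0 <= ii < n and 0 <= jj < r and 0 <= kk < c) or not occ[ii, jj, kk]:
                out.add((int(i), int(j), int(k)))
                break
    return out


def frustum_sum_oracle(areas_mm2, dx: float) -> float:
    """Closed-form frustum sum over a single-region slice-area sequence, mm^3.

    Pads the sequence with zero-area virtual slices at both ends and sums
    (1/3)(A + B + sqrt(A B)) dX over consecutive pairs.
    """
    padded = [0.0, *areas_mm2, 0.0]
    total = 0.0
    for a, b in zip(padded[:-1], padded[1:]):
        total += (a + b + (a * b) ** 0.5) * dx / 3.0
    return total


def wilcoxon_exact_oracle(d: np.ndarray, alternative: str) -> float:
    """Exact one-sided signed-rank p-value by itertools enumeration."""
    from itertools import product

    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_obs = w_plus if alternative == "m1_greater" else ranks.sum() - w_plus
    count = 0
    total = 0
    for signs in product([0, 1], repeat=len(ranks)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        count += w >= w_obs - 1e-9
        total += 1
    return count / total


def spearman_rank_formula(x, y) -> float:
    """1 - 6*sum(d^2)/(n(n^2-1)) for tie-free data."""
    import numpy as np

    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d = rx - ry
    n = len(x)
    return 1 - 6 * float((d * d).sum()) / (n * (n * n - 1))
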