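"""Independent brute-force oracles for the test suite.

Everything here is written as plain nested loops over pixels, matrices and
formulas, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm_counts(levels, mask, direction, distance=1, n_levels=None):
    """Symmetric co-occurrence counts by enumerating every in-mask pixel pair."""
    ng = int(n_levels if n_levels else levels[mask].max())
    counts = np.zeros((ng, ng), dtype=int)
    h, w = levels.shape
    dr, dc = OFFSETS[direction]
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for sign in (+1, -1):
                rr, cc = r + sign * dr * distance, c + sign * dc * distance
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    counts[levels[r, c] - 1, levels[rr, cc] - 1] += 1
    return counts


def brute_glrlm_counts(levels, mask, direction, n_levels=None):
    """Run-length counts by walking every lattice line pixel by pixel."""
    ng = int(n_levels if n_levels else levels[mask].max())
    h, w = levels.shape
    counts = np.zeros((ng, max(h, w)), dtype=int)

    if direction == 0:
        lines = [[(r, c) for c in range(w)] for r in range(h)]
    elif direction == 90:
        lines = [[(r, c) for r in range(h)] for c in range(w)]
    elif direction == 135:
        lines = []
        for off in range(-(h - 1), w):
            line = [(r, r + off) for r in range(h) if 0 <= r + off < w]
            lines.append(line)
    elif direction == 45:
        lines = []
        for s in range(h + w - 1):
            line = [(r, s - r) for r in range(h) if 0 <= s - r < w]
            lines.append(line)

    for line in lines:
        cur_level, cur_len = None, 0
        for r, c in line:
            if mask[r, c] and levels[r, c] == cur_level:
                cur_len += 1
            else:
                if cur_len:
                    counts[cur_level - 1, cur_len - 1] += 1
                if mask[r, c]:
                    cur_level, cur_len = int(levels[r, c]), 1
                else:
                    cur_level, cur_len = None, 0
        if cur_len:
            counts[cur_level - 1, cur_len - 1] += 1
    return counts


def _plog2(x):
    return x * math.log2(x) if x > 0 else 0.0


def brute_glcm_features(counts):
    """The 18 co-occurrence features evaluated formula by formula with loops."""
    total = counts.sum()
    ng = counts.shape[0]
    p = counts / total
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng))

    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i, j]
            p_sum[i + j] += p[i, j]

    f = {}
    f["asm"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["autocorrelation"] = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    f["cluster_prominence"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 4 * p[i, j] for i in range(ng) for j in range(ng)
    )
    f["cluster_shade"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 3 * p[i, j] for i in range(ng) for j in range(ng)
    )
    f["contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    if var_x > 0 and var_y > 0:
        f["correlation"] = sum(
            (i + 1 - mu_x) * (j + 1 - mu_y) * p[i, j] for i in range(ng) for j in range(ng)
        ) / math.sqrt(var_x * var_y)
    else:
        f["correlation"] = 1.0
    f["difference_entropy"] = -sum(_plog2(q) for q in p_diff)
    mu_d = sum(k * p_diff[k] for k in range(ng))
    f["difference_variance"] = sum((k - mu_d) ** 2 * p_diff[k] for k in range(ng))
    f["dissimilarity"] = sum(abs(i - j) * p[i, j] for i in range(ng) for j in range(ng))
    hxy = -sum(_plog2(p[i, j]) for i in range(ng) for j in range(ng))
    f["entropy"] = hxy
    hx = -sum(_plog2(q) for q in px)
    hy = -sum(_plog2(q) for q in py)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if p[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(_plog2(px[i] * py[j]) for i in range(ng) for j in range(ng))
    f["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    if hx == 0 and hy == 0:
        f["imc2"] = 0.0
    else:
        f["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["idm"] = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["maximum_probability"] = p.max()
    sa = sum((k + 2) * p_sum[k] for k in range(2 * ng - 1))
    f["sum_average"] = sa
    f["sum_entropy"] = -sum(_plog2(q) for q in p_sum)
    f["sum_variance"] = sum((k + 2 - sa) ** 2 * p_sum[k] for k in range(2 * ng - 1))
    f["variance"] = sum((i + 1 - mu_x) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    return f


def brute_glrlm_features(counts, n_pixels):
    """The 11 run-length features evaluated with explicit loops."""
    ng, lmax = counts.shape
    ns = counts.sum()
    f = {}
    f["short_run_emphasis"] = sum(
        counts[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(lmax)
    ) / ns
    f["long_run_emphasis"] = sum(
        counts[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(lmax)
    ) / ns
    f["lglre"] = sum(counts[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(lmax)) / ns
    f["hglre"] = sum(counts[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(lmax)) / ns
    f["srlgle"] = sum(
        counts[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(lmax)
    ) / ns
    f["srhgle"] = sum(
        counts[i, j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(lmax)
    ) / ns
    f["lrlgle"] = sum(
        counts[i, j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(lmax)
    ) / ns
    f["lrhgle"] = sum(
        counts[i, j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(lmax)
    ) / ns
    f["glnu"] = sum(sum(counts[i, j] for j in range(lmax)) ** 2 for i in range(ng)) / ns
    f["rlnu"] = sum(sum(counts[i, j] for i in range(ng)) ** 2 for j in range(lmax)) / ns
    f["run_percentage"] = ns / n_pixels
    return f


def brute_bh(pvals):
    """Benjamini-Hochberg step-up, straight from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank, 1.0)
        adj[i] = val
        prev = val
    return adj


def brute_mwu_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating every group labeling."""
    from itertools import combinations

    pooled = list(x) + list(y)
    nx = len(x)
    n = len(pooled)

    def ustat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in idx]
        u = 0.0
        for a in xs:
            for b in ys:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    mean_u = nx * (n - nx) / 2.0
    obs = abs(ustat(tuple(range(nx))) - mean_u)
    hits = total = 0
    for pick in combinations(range(n), nx):
        total += 1
        if abs(ustat(pick) - mean_u) >= obs - 1e-12:
            hits += 1
    return hits / total
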