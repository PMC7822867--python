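"""Grey-level co-occurrence and run-length texture features.

The "2D average" scheme: VOI intensities are discretized into ``Ng`` equal
width bins spanning the VOI's min-max (fixed bin number quantization, whole
3D VOI so all slices share one grey scale); GLCMs and GLRLMs are built per
axial slice at one-pixel distance in the four symmetric directions 0, 45,
90 and 135 degrees; features are computed per directional matrix, averaged
over slices within each direction, then averaged over the four directions.

Feature definitions follow the image biomarker standardisation initiative
conventions, with all entropy-type features in log base 2 and 0*log(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import VoiSample

DIRECTIONS = (0, 45, 90, 135)
# (row, col) offsets; rows grow downward, so 45 deg is up-right.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_FEATURE_NAMES = (
    "asm",
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "contrast",
    "correlation",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "entropy",
    "imc1",
    "imc2",
    "idm",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "variance",
)

GLRLM_FEATURE_NAMES = (
    "glnu",
    "hglre",
    "lglre",
    "long_run_emphasis",
    "lrhgle",
    "lrlgle",
    "rlnu",
    "run_percentage",
    "short_run_emphasis",
    "srhgle",
    "srlgle",
)

TEXTURE_FEATURE_NAMES = GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES


@dataclass
class QuantizedVoi:
    """Per-slice integer grey levels in 1..Ng plus the shared bin edges."""

    slices: list[tuple[np.ndarray, np.ndarray]]
    n_levels: int
    bin_edges: np.ndarray


@dataclass
class CooccurrenceMatrix:
    """Normalized symmetric GLCM for one (slice, direction)."""

    p: np.ndarray
    direction: int
    distance: int
    n_pairs: int


@dataclass
class RunLengthMatrix:
    """Raw GLRLM for one (slice, direction); r[i-1, j-1] counts runs of level i, length j."""

    r: np.ndarray
    direction: int
    n_pixels: int
    n_runs: int


def quantize_fbn(sample: VoiSample, n_levels: int = 32) -> QuantizedVoi:
    """Fixed-bin-number quantization of a VOI into ``n_levels`` grey levels.

    Equal-width bins span the min-max of the kept (post-exclusion) values of
    the whole 3D VOI; the maximum maps to level ``n_levels``; a constant VOI
    maps entirely to level 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    vmin = float(np.min(sample.values))
    vmax = float(np.max(sample.values))
    if vmax == vmin:
        edges = np.linspace(vmin, vmin + 1.0, n_levels + 1)
        out = [
            (np.where(msk, 1, 0).astype(np.int64), msk.copy())
            for _, msk in sample.slices
        ]
        return QuantizedVoi(slices=out, n_levels=n_levels, bin_edges=edges)
    edges = np.linspace(vmin, vmax, n_levels + 1)
    width = (vmax - vmin) / n_levels
    out = []
    for img2d, msk2d in sample.slices:
        lev = np.floor((img2d - vmin) / width).astype(np.int64) + 1
        np.clip(lev, 1, n_levels, out=lev)
        lev[~msk2d] = 0
        out.append((lev, msk2d.copy()))
    return QuantizedVoi(slices=out, n_levels=n_levels, bin_edges=edges)


def glcm(
    slice_levels: np.ndarray,
    mask: np.ndarray,
    direction: int,
    distance: int = 1,
    n_levels: int | None = None,
) -> CooccurrenceMatrix:
    """Symmetric normalized grey-level co-occurrence matrix for one slice.

    Ordered level pairs are counted at the direction's offset with both
    endpoints in-mask, symmetrized by adding the transpose, and normalized.
    ``n_pairs`` is the symmetric count before normalization; a slice with no
    valid pair is flagged with ``n_pairs = 0`` and skipped by aggregation.
    """
    if not mask.any():
        raise ValueError("empty slice mask")
    ng = int(n_levels if n_levels is not None else max(slice_levels[mask].max(), 1))
    dr, dc = _OFFSETS[direction]
    h, w = slice_levels.shape
    r0s, r0e = max(0, -dr * distance), min(h, h - dr * distance)
    c0s, c0e = max(0, -dc * distance), min(w, w - dc * distance)
    a = slice_levels[r0s:r0e, c0s:c0e]
    am = mask[r0s:r0e, c0s:c0e]
    b = slice_levels[r0s + dr * distance : r0e + dr * distance, c0s + dc * distance : c0e + dc * distance]
    bm = mask[r0s + dr * distance : r0e + dr * distance, c0s + dc * distance : c0e + dc * distance]
    ok = am & bm
    counts = np.zeros((ng, ng), dtype=np.int64)
    if ok.any():
        ai = a[ok] - 1
        bi = b[ok] - 1
        np.add.at(counts, (ai, bi), 1)
    sym = counts + counts.T
    n_pairs = int(sym.sum())
    p = sym / n_pairs if n_pairs > 0 else sym.astype(float)
    return CooccurrenceMatrix(p=p, direction=direction, distance=distance, n_pairs=n_pairs)


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def glcm_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """The 18 co-occurrence features from a normalized symmetric GLCM."""
    if m.n_pairs <= 0:
        raise ValueError("empty co-occurrence matrix")
    p = m.p
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    # diagonal (difference) and cross-diagonal (sum) probabilities
    k_diff = np.arange(ng, dtype=float)  # |i-j| = 0..Ng-1
    p_diff = np.zeros(ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)  # i+j = 2..2Ng
    p_sum = np.zeros(2 * ng - 1)
    absdiff = np.abs(ii - jj).astype(int)
    sums = (ii + jj).astype(int)
    np.add.at(p_diff, absdiff.ravel(), p.ravel())
    np.add.at(p_sum, sums.ravel() - 2, p.ravel())

    asm = float((p**2).sum())
    autocorr = float((ii * jj * p).sum())
    cdev = ii + jj - mu_x - mu_y
    cluster_prom = float((cdev**4 * p).sum())
    cluster_shade = float((cdev**3 * p).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float((((ii - mu_x) * (jj - mu_y) * p).sum()) / np.sqrt(var_x * var_y))
    else:
        correlation = 1.0  # constant slice: perfect (degenerate) correlation
    diff_avg = float((k_diff * p_diff).sum())
    diff_entropy = _entropy2(p_diff)
    diff_variance = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    dissimilarity = float((np.abs(ii - jj) * p).sum())
    hxy = _entropy2(p)
    hx = _entropy2(px)
    hy = _entropy2(py)
    outer = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = float(-(p * log_outer).sum())
    hxy2 = float(-(outer * log_outer).sum())
    hmax = max(hx, hy)
    imc1 = (hxy - hxy1) / hmax if hmax > 0 else 0.0
    if hx == 0 and hy == 0:
        imc2 = 0.0
    else:
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    max_prob = float(p.max())
    sum_average = float((k_sum * p_sum).sum())
    sum_entropy = _entropy2(p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    # joint grey-level variance; with a symmetric matrix mu_x == mu_y
    variance = float(((ii - mu_x) ** 2 * p).sum())

    return {
        "asm": asm,
        "autocorrelation": autocorr,
        "cluster_prominence": cluster_prom,
        "cluster_shade": cluster_shade,
        "contrast": contrast,
        "correlation": correlation,
        "difference_entropy": diff_entropy,
        "difference_variance": diff_variance,
        "dissimilarity": dissimilarity,
        "entropy": hxy,
        "imc1": imc1,
        "imc2": imc2,
        "idm": idm,
        "maximum_probability": max_prob,
        "sum_average": sum_average,
        "sum_entropy": sum_entropy,
        "sum_variance": sum_variance,
        "variance": variance,
    }


def _lines_for_direction(shape: tuple[int, int], direction: int):
    """Yield index arrays (rows, cols) tracing each maximal lattice line."""
    h, w = shape
    if direction == 0:  # along columns, one line per row
        for r in range(h):
            yield np.full(w, r), np.arange(w)
    elif direction == 90:  # along rows, one line per column
        for c in range(w):
            yield np.arange(h), np.full(h, c)
    elif direction == 135:  # main diagonals (down-right traversal)
        for off in range(-(h - 1), w):
            n = min(h, w, h + off, w - off)
            r = np.arange(max(0, -off), max(0, -off) + n)
            c = np.arange(max(0, off), max(0, off) + n)
            yield r, c
    elif direction == 45:  # anti-diagonals (down-left traversal)
        for s in range(h + w - 1):
            r = np.arange(max(0, s - w + 1), min(h, s + 1))
            c = s - r
            yield r, c
    else:
        raise ValueError(f"unsupported direction {direction}")


def glrlm(
    slice_levels: np.ndarray,
    mask: np.ndarray,
    direction: int,
    n_levels: int | None = None,
) -> RunLengthMatrix:
    """Grey-level run-length matrix: maximal constant-level runs along a direction.

    Runs break at mask boundaries; every in-mask pixel belongs to exactly one
    run per direction.
    """
    if not mask.any():
        raise ValueError("empty slice mask")
    ng = int(n_levels if n_levels is not None else max(slice_levels[mask].max(), 1))
    lmax = max(slice_levels.shape)
    counts = np.zeros((ng, lmax), dtype=np.int64)
    for rows, cols in _lines_for_direction(slice_levels.shape, direction):
        lev = slice_levels[rows, cols]
        ok = mask[rows, cols]
        run_level, run_len = 0, 0
        for v, o in zip(lev, ok):
            if o and v == run_level:
                run_len += 1
            else:
                if run_len:
                    counts[run_level - 1, run_len - 1] += 1
                run_level, run_len = (int(v), 1) if o else (0, 0)
        if run_len:
            counts[run_level - 1, run_len - 1] += 1
    n_runs = int(counts.sum())
    n_pixels = int(mask.sum())
    # trim trailing all-zero lengths, keep at least one column
    used = np.nonzero(counts.any(axis=0))[0]
    if used.size:
        counts = counts[:, : used.max() + 1]
    else:
        counts = counts[:, :1]
    return RunLengthMatrix(r=counts, direction=direction, n_pixels=n_pixels, n_runs=n_runs)


def glrlm_features(m: RunLengthMatrix) -> dict[str, float]:
    """The 11 run-length features from a raw GLRLM."""
    if m.n_runs <= 0:
        raise ValueError("empty run-length matrix")
    r = m.r.astype(float)
    ng, lmax = r.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, lmax + 1, dtype=float)[None, :]
    ns = float(m.n_runs)
    ri = r.sum(axis=1)
    rj = r.sum(axis=0)
    jv = np.arange(1, lmax + 1, dtype=float)
    iv = np.arange(1, ng + 1, dtype=float)
    return {
        "glnu": float((ri**2).sum() / ns),
        "hglre": float((ri * iv**2).sum() / ns),
        "lglre": float((ri / iv**2).sum() / ns),
        "long_run_emphasis": float((rj * jv**2).sum() / ns),
        "lrhgle": float((r * i**2 * j**2).sum() / ns),
        "lrlgle": float((r * j**2 / i**2).sum() / ns),
        "rlnu": float((rj**2).sum() / ns),
        "run_percentage": ns / float(m.n_pixels),
        "short_run_emphasis": float((rj / jv**2).sum() / ns),
        "srhgle": float((r * i**2 / j**2).sum() / ns),
        "srlgle": float((r / (i**2 * j**2)).sum() / ns),
    }


def aggregate_2d_average(
    per_cell: dict[tuple[int, int], dict[str, float]],
) -> dict[str, float]:
    """Nested 2D-average: mean over slices within each direction, then over directions.

    ``per_cell`` maps ``(slice_index, direction)`` to a feature dict; empty
    cells are simply absent. Directions with no valid slice drop out of the
    outer mean.
    """
    if not per_cell:
        raise ValueError("VOI too small for texture")
    by_dir: dict[int, list[dict[str, float]]] = {}
    for (_, theta), feats in per_cell.items():
        by_dir.setdefault(theta, []).append(feats)
    names = next(iter(per_cell.values())).keys()
    out = {}
    for name in names:
        dir_means = [float(np.mean([f[name] for f in cells])) for cells in by_dir.values()]
        out[name] = float(np.mean(dir_means))
    return out


def texture_features(
    sample: VoiSample, n_levels: int = 32, distance: int = 1
) -> dict[str, float]:
    """Full per-tumor texture pipeline: quantize, per-(slice, direction)
    GLCM/GLRLM features, nested 2D-average aggregation."""
    q = quantize_fbn(sample, n_levels=n_levels)
    per_cell: dict[tuple[int, int], dict[str, float]] = {}
    for s_idx, (lev, msk) in enumerate(q.slices):
        if not msk.any():
            continue
        for theta in DIRECTIONS:
            c = glcm(lev, msk, theta, distance=distance, n_levels=n_levels)
            if c.n_pairs == 0:
                continue
            feats = glcm_features(c)
            rl = glrlm(lev, msk, theta, n_levels=n_levels)
            feats.update(glrlm_features(rl))
            per_cell[(s_idx, theta)] = feats
    return aggregate_2d_average(per_cell)
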