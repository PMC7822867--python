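"""T2W intensity normalization, outlier exclusion and VOI assembly.

T2W intensities are arbitrary-scale; the dual-reference normalization maps
them to pseudo-T2 values (ms) through the unique line sending the fat
reference intensity (90th percentile of a fat region) to the literature T2
of fat and the muscle reference intensity (10th percentile of a muscle
region) to the T2 of muscle. Because a per-scanner intensity effect is, to
good approximation, affine, and the references are measured on the same
volume, this mapping cancels the site effect exactly in the affine
noise-free case.

ADC maps are quantitative and are not normalized; the in-VOI outlier rule
([mu - 3 sigma, mu + 3 sigma], single pass) applies to both modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ImageVolume, VoiMask, check_aligned

# Pseudo-T2 anchors (ms) at 3T. The normalization method takes these from
# the relaxometry literature; the exact values are configurable and only
# fix the output scale, not any downstream statistic.
DEFAULT_T2_FAT_MS = 121.0
DEFAULT_T2_MUSCLE_MS = 40.0


def normalize_dual_reference(
    volume: ImageVolume,
    fat_ref: float,
    muscle_ref: float,
    t2_fat: float = DEFAULT_T2_FAT_MS,
    t2_muscle: float = DEFAULT_T2_MUSCLE_MS,
) -> ImageVolume:
    """Map raw T2W intensities to pseudo-T2 via the two-point linear map.

    The affine map is the unique line through ``(fat_ref, t2_fat)`` and
    ``(muscle_ref, t2_muscle)``, applied voxelwise.
    """
    if fat_ref == muscle_ref:
        raise ValueError("degenerate references: fat_ref == muscle_ref")
    if t2_fat == t2_muscle:
        raise ValueError("degenerate references: t2_fat == t2_muscle")
    slope = (t2_fat - t2_muscle) / (fat_ref - muscle_ref)
    data = t2_muscle + slope * (volume.data - muscle_ref)
    return ImageVolume(data=data, spacing=volume.spacing, modality=volume.modality)


def exclude_outliers(
    values: np.ndarray, ddof: int = 1
) -> tuple[np.ndarray, int, float, float]:
    """Single-pass mu +/- 3 sigma exclusion.

    mu and sigma are computed on the *input* values (sample SD by default,
    ``ddof=0`` for the population convention); values outside
    ``[mu - 3 sigma, mu + 3 sigma]`` are dropped in one pass, with no
    re-estimation. A constant input (sigma = 0) is returned unchanged.

    Returns ``(kept, n_excluded, mu, sigma)``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 values for outlier screening")
    mu = float(values.mean())
    sigma = float(values.std(ddof=ddof))
    if sigma == 0.0:
        return values.copy(), 0, mu, sigma
    keep = (values >= mu - 3.0 * sigma) & (values <= mu + 3.0 * sigma)
    return values[keep], int((~keep).sum()), mu, sigma


@dataclass
class VoiSample:
    """The masked voxel set of one tumor after outlier exclusion.

    ``slices`` holds, for every axial slice intersecting the mask, a 2D
    intensity crop and the aligned 2D boolean mask (with excluded voxels
    removed); ``values`` is the flat list of kept in-mask intensities.
    """

    values: np.ndarray
    slices: list[tuple[np.ndarray, np.ndarray]]
    n_excluded: int
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("VOI sample has no kept voxels")


def extract_voi(volume: ImageVolume, mask: VoiMask, ddof: int = 1) -> VoiSample:
    """Assemble the per-tumor masked sample with outlier exclusion.

    Exclusion runs once on the flat in-mask value list of the whole 3D VOI
    and is propagated into the per-slice masks, so texture slices never see
    excluded voxels. Conservation: ``len(values) + n_excluded`` equals the
    mask voxel count.
    """
    check_aligned(volume, mask)
    m3 = mask.data
    flat = volume.data[m3]
    if flat.size == 0:
        raise ValueError("empty mask")
    if flat.size == 1:
        kept_mask3 = m3
        values, n_excluded, mu, sigma = flat.copy(), 0, float(flat[0]), 0.0
    else:
        _, n_excluded, mu, sigma = exclude_outliers(flat, ddof=ddof)
        if sigma == 0.0:
            inlier = np.ones_like(flat, dtype=bool)
        else:
            inlier = (flat >= mu - 3.0 * sigma) & (flat <= mu + 3.0 * sigma)
        kept_mask3 = np.zeros_like(m3)
        kept_mask3[m3] = inlier
        values = flat[inlier]

    # Per-slice crops over the ORIGINAL mask's axial extent and in-plane
    # bounding box, with the post-exclusion mask aligned to each crop.
    rows, cols, slcs = np.nonzero(m3)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    slices: list[tuple[np.ndarray, np.ndarray]] = []
    for z in sorted(np.unique(slcs)):
        img2d = volume.data[r0:r1, c0:c1, z]
        msk2d = kept_mask3[r0:r1, c0:c1, z]
        slices.append((img2d.copy(), msk2d.copy()))

    return VoiSample(values=values, slices=slices, n_excluded=n_excluded, mu=mu, sigma=sigma)
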