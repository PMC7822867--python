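"""Per-tumor feature extraction into a cohort feature table.

Each row is one tumor; columns are 11 ADC histogram features (``adc_``),
11 normalized-T2W histogram features (``t2w_``) and 29 T2W texture features
(``t2w_``: 18 co-occurrence + 11 run-length), plus metadata (patient,
institution, grade group, aggressiveness class).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adc import DwSeries, fit_adc_map
from .histogram import HISTOGRAM_FEATURE_NAMES, histogram_features
from .io import ImageVolume, VoiMask
from .preprocessing import (
    DEFAULT_T2_FAT_MS,
    DEFAULT_T2_MUSCLE_MS,
    extract_voi,
    normalize_dual_reference,
)
from .texture import TEXTURE_FEATURE_NAMES, texture_features

METADATA_COLUMNS = ("patient_id", "site_id", "tumor_id", "grade_group", "aggressiveness")

ADC_HISTOGRAM_COLUMNS = tuple(f"adc_{n}" for n in HISTOGRAM_FEATURE_NAMES)
T2W_HISTOGRAM_COLUMNS = tuple(f"t2w_{n}" for n in HISTOGRAM_FEATURE_NAMES)
T2W_TEXTURE_COLUMNS = tuple(f"t2w_{n}" for n in TEXTURE_FEATURE_NAMES)
FEATURE_COLUMNS = ADC_HISTOGRAM_COLUMNS + T2W_HISTOGRAM_COLUMNS + T2W_TEXTURE_COLUMNS

# The classifier comparison evaluates these six feature sets.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "adc_hist": ADC_HISTOGRAM_COLUMNS,
    "t2w_hist": T2W_HISTOGRAM_COLUMNS,
    "t2w_texture": T2W_TEXTURE_COLUMNS,
    "t2w_hist_texture": T2W_HISTOGRAM_COLUMNS + T2W_TEXTURE_COLUMNS,
    "adc_t2w_hist": ADC_HISTOGRAM_COLUMNS + T2W_HISTOGRAM_COLUMNS,
    "adc_t2w_hist_texture": FEATURE_COLUMNS,
}


def extract_tumor_features(
    t2w: ImageVolume,
    dw: DwSeries,
    mask: VoiMask,
    fat_ref: float,
    muscle_ref: float,
    t2_fat: float = DEFAULT_T2_FAT_MS,
    t2_muscle: float = DEFAULT_T2_MUSCLE_MS,
    n_levels: int = 32,
) -> dict[str, float]:
    """Run the full per-tumor pipeline and return the named feature map.

    T2W intensities are normalized to pseudo-T2 before feature extraction;
    ADC values are used as fitted (quantitative, not normalized). The
    mu +/- 3 sigma outlier rule applies to both VOI samples.
    """
    pseudo_t2 = normalize_dual_reference(t2w, fat_ref, muscle_ref, t2_fat, t2_muscle)
    t2_sample = extract_voi(pseudo_t2, mask)
    adc_map = fit_adc_map(dw)
    adc_sample = extract_voi(adc_map, mask)

    feats: dict[str, float] = {}
    feats.update(histogram_features(adc_sample.values, prefix="adc"))
    feats.update(histogram_features(t2_sample.values, prefix="t2w"))
    feats.update({f"t2w_{k}": v for k, v in texture_features(t2_sample, n_levels=n_levels).items()})
    return feats


def dichotomize(grade_group: int) -> str:
    """ISUP grade group 1 is low-aggressive; grade group >= 2 is intermediate/high."""
    if grade_group not in (1, 2, 3, 4, 5):
        raise ValueError(f"grade group must be 1..5, got {grade_group}")
    return "low" if grade_group == 1 else "int_high"


def build_feature_table(cohort, n_levels: int = 32) -> pd.DataFrame:
    """Extract features for every tumor of a synthetic cohort."""
    rows = []
    for t in cohort.tumors:
        feats = extract_tumor_features(
            t.t2w, t.dw, t.mask, t.fat_ref, t.muscle_ref, n_levels=n_levels
        )
        row = {
            "patient_id": t.spec.patient_id,
            "site_id": t.spec.site_id,
            "tumor_id": t.spec.tumor_id,
            "grade_group": t.spec.grade_group,
            "aggressiveness": dichotomize(t.spec.grade_group),
        }
        row.update(feats)
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + list(FEATURE_COLUMNS))
    return table


def build_feature_table_from_manifest(manifest: pd.DataFrame, n_levels: int = 32) -> pd.DataFrame:
    """Extract features for a cohort stored on disk (see the manifest schema
    written by :func:`pzrad.synthetic.write_cohort`)."""
    from .io import read_dw_series, read_mask, read_volume

    rows = []
    for _, rec in manifest.iterrows():
        t2w = read_volume(rec["t2w_path"], modality="t2w")
        mask = read_mask(rec["mask_path"], tumor_id=str(rec["tumor_id"]))
        dw = read_dw_series(rec["dw_path"], rec["bval_path"])
        feats = extract_tumor_features(
            t2w, dw, mask, float(rec["fat_ref"]), float(rec["muscle_ref"]), n_levels=n_levels
        )
        row = {
            "patient_id": rec["patient_id"],
            "site_id": rec["site_id"],
            "tumor_id": rec["tumor_id"],
            "grade_group": int(rec["grade_group"]),
            "aggressiveness": dichotomize(int(rec["grade_group"])),
        }
        row.update(feats)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + list(FEATURE_COLUMNS))
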