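"""Synthetic multi-site prostate MRI cohort generator.

Real multiparametric prostate MRI with whole-mount-histology VOIs is not
publicly available at the scale this pipeline needs, so this module
generates a cohort with the statistical structure the analysis assumes:

* two aggressiveness classes (ISUP grade group 1 vs >= 2) that differ in
  textural structure — low-grade tumors are smoother (longer spatial
  correlation length, less independent noise), high-grade tumors are more
  disordered — and in ADC level (lower in aggressive tumors);
* an exactly affine per-site intensity effect (gain, offset) on raw T2W
  intensities, so dual-reference normalization can cancel it;
* embedded fat and muscle reference regions whose 90th / 10th percentile
  intensities are known exactly;
* a co-registered DW series following S(b) = S0 exp(-b ADC) per voxel;
* an imbalanced six-site cohort (default: 87 patients, ~104 tumors,
  roughly 30 low vs 74 intermediate/high).

Everything is deterministic under (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .adc import DwSeries
from .io import ImageVolume, VoiMask, write_dw_series, write_mask, write_volume

GG_LOW = 1
# Grade-group mix among intermediate/high tumors, close to the observed
# multicenter distribution (36:26:6:6 for GG 2:3:4:5).
INT_HIGH_GG_PROBS = {2: 36 / 74, 3: 26 / 74, 4: 6 / 74, 5: 6 / 74}


@dataclass
class SiteProfile:
    """One institution: its affine intensity effect and patient mix."""

    site_id: str
    gain: float
    offset: float
    n_patients: int
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"low": 0.3, "int_high": 0.7}
    )

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"site {self.site_id}: gain must be positive")
        if self.n_patients < 1:
            raise ValueError(f"site {self.site_id}: n_patients must be >= 1")
        total = sum(self.class_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"site {self.site_id}: class proportions sum to {total}, not 1")


@dataclass
class TumorSpec:
    patient_id: str
    site_id: str
    grade_group: int
    zone: str
    n_voxels: int
    texture_corr_length: float
    noise_sd: float
    adc_mean: float
    tumor_id: str = ""


@dataclass
class TumorRecord:
    spec: TumorSpec
    t2w: ImageVolume
    dw: DwSeries
    mask: VoiMask
    fat_ref: float
    muscle_ref: float


@dataclass
class CohortConfig:
    """Generator settings; the defaults are the package's study conditions."""

    sites: list[SiteProfile] = field(default_factory=lambda: default_sites())
    volume_shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (0.6, 0.6, 3.6)
    bvalues: tuple[float, ...] = (0.0, 100.0, 400.0, 800.0)
    voxel_range: tuple[int, int] = (101, 1397)
    target_voxel_range: tuple[int, int] = (140, 1250)
    prob_second_tumor: float = 0.2
    # T2W texture model (raw units, before site gain/offset)
    tumor_t2_level: float = 400.0
    texture_amplitude: float = 0.18
    corr_length_by_gg: dict[int, float] = field(
        default_factory=lambda: {1: 3.0, 2: 1.65, 3: 1.5, 4: 1.35, 5: 1.2}
    )
    noise_sd_by_gg: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.12, 3: 0.14, 4: 0.16, 5: 0.18}
    )
    background_level: float = 300.0
    background_noise_sd: float = 15.0
    # Reference tissues (raw units, before gain/offset)
    fat_true: float = 800.0
    muscle_true: float = 200.0
    # ADC model (mm^2/s)
    adc_by_gg: dict[int, float] = field(
        default_factory=lambda: {1: 1.5e-3, 2: 0.95e-3, 3: 0.85e-3, 4: 0.75e-3, 5: 0.65e-3}
    )
    adc_between_tumor_sd: float = 0.08e-3
    adc_within_tumor_sd: float = 0.05e-3
    adc_background: float = 1.8e-3
    dw_s0: float = 1000.0
    dw_noise_sd: float = 5.0
    dw_noise_model: str = "gaussian"  # or "rician"

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "sites" in d:
            d["sites"] = [SiteProfile(**s) for s in d["sites"]]
        for key in ("volume_shape", "spacing", "bvalues", "voxel_range", "target_voxel_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("corr_length_by_gg", "noise_sd_by_gg", "adc_by_gg"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)


def default_sites() -> list[SiteProfile]:
    """Six institutions mirroring the multicenter cohort's imbalance:
    87 patients, per-site low-class proportions taken from the observed
    tumor grade mix, and distinct affine intensity effects."""
    lows = {"A": 5 / 19, "B": 1 / 17, "C": 10 / 27, "D": 3 / 20, "E": 6 / 10, "F": 5 / 11}
    n_pat = {"A": 17, "B": 15, "C": 21, "D": 16, "E": 8, "F": 10}
    gains = {"A": 1.0, "B": 1.3, "C": 0.8, "D": 1.15, "E": 0.9, "F": 1.2}
    offsets = {"A": 0.0, "B": 20.0, "C": -15.0, "D": 10.0, "E": 5.0, "F": -10.0}
    return [
        SiteProfile(
            site_id=s,
            gain=gains[s],
            offset=offsets[s],
            n_patients=n_pat[s],
            class_proportions={"low": lows[s], "int_high": 1 - lows[s]},
        )
        for s in "ABCDEF"
    ]


def null_config(n_patients_per_site: int = 6) -> CohortConfig:
    """A cohort with NO class effect: texture, noise and ADC parameters are
    identical across grade groups, while the per-site affine intensity
    effects and the class imbalance remain. Used for null calibration of the
    classifier evaluation; smaller than the default cohort because it is run
    over many seeds."""
    sites = [
        SiteProfile(
            site_id=s.site_id,
            gain=s.gain,
            offset=s.offset,
            n_patients=n_patients_per_site,
            class_proportions={"low": 0.3, "int_high": 0.7},
        )
        for s in default_sites()
    ]
    return CohortConfig(
        sites=sites,
        corr_length_by_gg={g: 2.0 for g in range(1, 6)},
        noise_sd_by_gg={g: 0.10 for g in range(1, 6)},
        adc_by_gg={g: 1.1e-3 for g in range(1, 6)},
    )


@dataclass
class SyntheticCohort:
    tumors: list[TumorRecord]
    seed: int
    config: CohortConfig

    def manifest(self) -> "pd.DataFrame":
        import pandas as pd

        rows = [
            {
                "patient_id": t.spec.patient_id,
                "site_id": t.spec.site_id,
                "tumor_id": t.spec.tumor_id,
                "grade_group": t.spec.grade_group,
                "zone": t.spec.zone,
                "n_voxels": t.spec.n_voxels,
                "fat_ref": t.fat_ref,
                "muscle_ref": t.muscle_ref,
            }
            for t in self.tumors
        ]
        return pd.DataFrame(rows)


def synthesize_texture_field(
    corr_length: float,
    noise_sd: float,
    shape: tuple[int, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary correlated random field: unit-variance smoothed white noise
    plus independent noise of standard deviation ``noise_sd``.

    Larger ``corr_length`` (the Gaussian smoothing width, in pixels) gives a
    smoother field, hence higher GLCM ASM/IDM and lower entropy after
    quantization; ``noise_sd`` adds grey-level disorder.
    """
    if corr_length <= 0:
        raise ValueError("texture_corr_length must be positive")
    if any(s <= 0 for s in shape):
        raise ValueError("non-positive field shape")
    white = rng.standard_normal(shape)
    # smooth in-plane only: slices are thick and gapped, texture is 2D
    sigmas = (corr_length, corr_length) + (0,) * (len(shape) - 2)
    smooth = gaussian_filter(white, sigma=sigmas, mode="wrap")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    if noise_sd > 0:
        smooth = smooth + noise_sd * rng.standard_normal(shape)
    return smooth


def embed_reference_tissues(
    volume: ImageVolume,
    fat_true: float,
    muscle_true: float,
    rng: np.random.Generator,
    tumor_mask: VoiMask | None = None,
) -> tuple[ImageVolume, float, float]:
    """Insert fat and muscle reference regions with exact percentile anchors.

    Two corner boxes are filled with jittered intensities rescaled so the
    fat region's 90th percentile equals ``fat_true`` and the muscle region's
    10th percentile equals ``muscle_true`` exactly (raw units, before any
    site gain/offset). Returns the modified volume and the two reference
    intensities as measured on it.
    """
    if not (fat_true > muscle_true > 0):
        raise ValueError("need fat_true > muscle_true > 0")
    data = volume.data.copy()
    h, w, d = data.shape
    bz = slice(0, min(2, d))
    fat_region = (slice(1, 7), slice(1, 7), bz)
    muscle_region = (slice(1, 7), slice(w - 7, w - 1), bz)
    if tumor_mask is not None:
        for region in (fat_region, muscle_region):
            probe = np.zeros(data.shape, dtype=bool)
            probe[region] = True
            if (probe & tumor_mask.data).any():
                raise ValueError("reference region overlaps the tumor mask")
    fat_vals = fat_true * (1.0 + 0.05 * rng.standard_normal(data[fat_region].shape))
    p90 = np.percentile(fat_vals, 90)
    fat_vals *= fat_true / p90
    data[fat_region] = fat_vals
    mus_vals = muscle_true * (1.0 + 0.05 * rng.standard_normal(data[muscle_region].shape))
    p10 = np.percentile(mus_vals, 10)
    mus_vals += muscle_true - p10
    data[muscle_region] = mus_vals
    out = ImageVolume(data=data, spacing=volume.spacing, modality=volume.modality)
    return out, float(fat_true), float(muscle_true)


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    rng: np.random.Generator,
    target_voxels: int,
    spacing_ratio: float,
) -> np.ndarray:
    """Axis-aligned jittered ellipsoid with roughly ``target_voxels`` voxels."""
    h, w, d = shape
    n_slices = int(rng.integers(2, min(6, d - 2)))
    c_half = n_slices / 2.0
    # in-plane semi-axes from the target volume of an ellipsoid
    ab = 3.0 * target_voxels / (4.0 * np.pi * c_half)
    ratio = rng.uniform(0.75, 1.3)
    a = np.sqrt(ab * ratio)
    b = np.sqrt(ab / ratio)
    margin = 10
    cr = rng.uniform(margin + a, h - margin - a)
    cc = rng.uniform(margin + b, w - margin - b)
    cz = rng.uniform(3 + c_half, d - 3 - c_half)
    rr, cc2, zz = np.meshgrid(np.arange(h), np.arange(w), np.arange(d), indexing="ij")
    val = ((rr - cr) / a) ** 2 + ((cc2 - cc) / b) ** 2 + ((zz - cz) / c_half) ** 2
    return val <= 1.0


def _make_tumor(
    spec: TumorSpec,
    site: SiteProfile,
    config: CohortConfig,
    rng: np.random.Generator,
) -> TumorRecord:
    shape = config.volume_shape

    # --- mask (retry until voxel count is in the configured range) ---
    lo, hi = config.voxel_range
    for _ in range(50):
        target = int(np.exp(rng.uniform(np.log(config.target_voxel_range[0]), np.log(config.target_voxel_range[1]))))
        m = _ellipsoid_mask(shape, rng, target, config.spacing[2] / config.spacing[0])
        if lo <= m.sum() <= hi:
            break
    else:  # pragma: no cover - extremely unlikely
        raise RuntimeError("could not draw a mask within the voxel range")
    mask = VoiMask(data=m, tumor_id=spec.tumor_id)
    spec.n_voxels = int(m.sum())

    # --- T2W: background + tumor texture field, then references, then site effect ---
    t2 = config.background_level + config.background_noise_sd * rng.standard_normal(shape)
    field3 = synthesize_texture_field(spec.texture_corr_length, spec.noise_sd, shape, rng)
    tumor_vals = config.tumor_t2_level * (1.0 + config.texture_amplitude * field3)
    t2[m] = tumor_vals[m]
    vol = ImageVolume(data=t2, spacing=config.spacing, modality="t2w")
    vol, fat_raw, muscle_raw = embed_reference_tissues(
        vol, config.fat_true, config.muscle_true, rng, tumor_mask=mask
    )
    t2_site = site.gain * vol.data + site.offset
    t2w = ImageVolume(data=t2_site, spacing=config.spacing, modality="t2w")
    fat_ref = site.gain * fat_raw + site.offset
    muscle_ref = site.gain * muscle_raw + site.offset

    # --- ADC truth and DW frames on the same grid ---
    adc = np.full(shape, config.adc_background)
    adc_field = gaussian_filter(rng.standard_normal(shape), sigma=(2, 2, 0), mode="wrap")
    sd = adc_field.std()
    if sd > 0:
        adc_field /= sd
    adc_tumor = spec.adc_mean + config.adc_within_tumor_sd * adc_field
    adc[m] = adc_tumor[m]
    np.clip(adc, 1e-5, None, out=adc)
    frames = []
    for b in config.bvalues:
        signal = config.dw_s0 * np.exp(-b * adc)
        if config.dw_noise_model == "rician":
            n1 = config.dw_noise_sd * rng.standard_normal(shape)
            n2 = config.dw_noise_sd * rng.standard_normal(shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
        else:
            signal = signal + config.dw_noise_sd * rng.standard_normal(shape)
        frames.append(ImageVolume(data=signal, spacing=config.spacing, modality="dw"))
    dw = DwSeries(frames=frames, bvalues=list(config.bvalues))

    return TumorRecord(spec=spec, t2w=t2w, dw=dw, mask=mask, fat_ref=fat_ref, muscle_ref=muscle_ref)


def generate_cohort(config: CohortConfig, seed: int) -> SyntheticCohort:
    """Generate the full multi-site cohort, deterministic under (config, seed)."""
    if len(config.sites) < 2:
        raise ValueError("config must list at least 2 sites")
    root = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])

    # draw patient classes and tumor specs first so degenerate cohorts fail fast
    specs: list[tuple[TumorSpec, SiteProfile]] = []
    class_counts = {"low": 0, "int_high": 0}
    gg_values = sorted(INT_HIGH_GG_PROBS)
    gg_probs = [INT_HIGH_GG_PROBS[g] for g in gg_values]
    for site in config.sites:
        for p in range(site.n_patients):
            patient_id = f"{site.site_id}{p:03d}"
            cls_names = list(site.class_proportions)
            cls = assign_rng.choice(cls_names, p=[site.class_proportions[c] for c in cls_names])
            n_tumors = 1 + int(assign_rng.random() < config.prob_second_tumor)
            for t in range(n_tumors):
                if cls == "low":
                    gg = GG_LOW
                else:
                    gg = int(assign_rng.choice(gg_values, p=gg_probs))
                class_counts[cls] += 1
                adc_mean = config.adc_by_gg[gg] + config.adc_between_tumor_sd * assign_rng.standard_normal()
                spec = TumorSpec(
                    patient_id=patient_id,
                    site_id=site.site_id,
                    grade_group=gg,
                    zone="peripheral",
                    n_voxels=0,
                    texture_corr_length=config.corr_length_by_gg[gg],
                    noise_sd=config.noise_sd_by_gg[gg],
                    adc_mean=float(np.clip(adc_mean, 0.3e-3, 2.5e-3)),
                    tumor_id=f"{patient_id}_t{t}",
                )
                specs.append((spec, site))
    if min(class_counts.values()) == 0:
        raise ValueError(f"degenerate cohort: class counts {class_counts}")

    children = root.spawn(len(specs) + 1)[1:]
    tumors = [
        _make_tumor(spec, site, config, np.random.default_rng(child))
        for (spec, site), child in zip(specs, children)
    ]
    return SyntheticCohort(tumors=tumors, seed=seed, config=config)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write the cohort to disk: one directory per patient with NIfTI volumes,
    DW series + b-value sidecars and masks, plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in cohort.tumors:
        pdir = out_dir / t.spec.patient_id
        pdir.mkdir(exist_ok=True)
        t2_path = pdir / f"{t.spec.tumor_id}_t2w.nii.gz"
        write_volume(t.t2w, t2_path)
        mask_path = pdir / f"{t.spec.tumor_id}_mask.nii.gz"
        write_mask(t.mask, t.t2w.spacing, mask_path)
        dw_path, bval_path = write_dw_series(t.dw.frames, t.dw.bvalues, pdir / f"{t.spec.tumor_id}_dw")
        rows.append(
            {
                "patient_id": t.spec.patient_id,
                "site_id": t.spec.site_id,
                "tumor_id": t.spec.tumor_id,
                "grade_group": t.spec.grade_group,
                "zone": t.spec.zone,
                "fat_ref": t.fat_ref,
                "muscle_ref": t.muscle_ref,
                "t2w_path": str(t2_path),
                "mask_path": str(mask_path),
                "dw_path": str(dw_path),
                "bval_path": str(bval_path),
            }
        )
    import pandas as pd

    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path
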