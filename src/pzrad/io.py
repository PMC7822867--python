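"""Image containers and file I/O.

Volumes are kept in voxel-index space: axes (row, col, slice), axial
slices along the last axis, 0-based indices. NIfTI is the on-disk image
format; feature tables and manifests are CSV; configuration is YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


@dataclass
class ImageVolume:
    """A 3D scalar volume with voxel spacing in mm.

    Parameters
    ----------
    data:
        3D array, axial slices along the last axis.
    spacing:
        Voxel size ``(dx, dy, dz)`` in mm, all positive.
    modality:
        One of ``"t2w"``, ``"dw"``, ``"adc"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.6, 0.6, 3.6)
    modality: str = "t2w"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with all dims >= 1, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class VoiMask:
    """Binary tumor volume-of-interest mask aligned to an :class:`ImageVolume`."""

    data: np.ndarray
    tumor_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask has no true voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI, encoding spacing in the affine."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), _affine_from_spacing(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, modality: str = "t2w") -> ImageVolume:
    """Read a 3D NIfTI file into an :class:`ImageVolume`."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"failed to read NIfTI volume at {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data=data, spacing=zooms, modality=modality)


def write_mask(mask: VoiMask, spacing: tuple[float, float, float], path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine_from_spacing(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, tumor_id: str = "") -> VoiMask:
    path = Path(path)
    img = nib.load(str(path))
    return VoiMask(data=np.asarray(img.dataobj) > 0, tumor_id=tumor_id)


def check_aligned(volume: ImageVolume, mask: VoiMask) -> None:
    """Raise if a mask and volume do not share a voxel grid."""
    if volume.shape != mask.data.shape:
        raise ValueError(
            f"mask shape {mask.data.shape} does not match volume shape {volume.shape}"
        )


def write_dw_series(frames: list[ImageVolume], bvalues: list[float], stem: str | Path) -> tuple[Path, Path]:
    """Write a DW series as 4D NIfTI plus an FSL-style b-value sidecar (one b per line)."""
    stem = Path(stem)
    data4d = np.stack([np.asarray(f.data, dtype=np.float32) for f in frames], axis=-1)
    img = nib.Nifti1Image(data4d, _affine_from_spacing(frames[0].spacing))
    nii_path = stem.with_suffix(".nii.gz")
    nib.save(img, str(nii_path))
    bval_path = stem.with_suffix(".bval")
    bval_path.write_text("\n".join(str(float(b)) for b in bvalues) + "\n")
    return nii_path, bval_path


def read_dw_series(nii_path: str | Path, bval_path: str | Path):
    """Read a 4D DW NIfTI and its b-value sidecar into a :class:`~pzrad.adc.DwSeries`."""
    from .adc import DwSeries  # local import avoids a cycle

    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nii_path}: expected 4D DW series, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    bvalues = [float(tok) for tok in Path(bval_path).read_text().split()]
    if len(bvalues) != data.shape[-1]:
        raise ValueError(
            f"{bval_path}: {len(bvalues)} b-values for {data.shape[-1]} frames"
        )
    frames = [ImageVolume(data=data[..., i], spacing=zooms, modality="dw") for i in range(data.shape[-1])]
    return DwSeries(frames=frames, bvalues=bvalues)


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (one row per tumor, with file paths and metadata)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"failed to parse manifest at {path}: {exc}") from exc
    required = {"patient_id", "site_id", "tumor_id", "grade_group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    return df
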