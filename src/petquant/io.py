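"""NIfTI image I/O and metric-table I/O for PET quantification.

SUV volumes and segmentation masks live on an axis-aligned voxel lattice
described by a per-axis spacing (mm) and the world position of the center of
voxel (0, 0, 0).  World coordinates follow the voxel-center convention:

    world_mm = origin_mm + index * spacing_mm   (0-based indices)

Only axis-aligned NIfTI geometries are supported: the rotation block of the
affine may permute or flip axes but must not shear or rotate.  On load,
images are reoriented so that spacing is positive along every axis, which
makes the (spacing, origin) description exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: per-axis tolerance when comparing voxel spacings (mm)
SPACING_ATOL_MM = 1e-3
#: per-axis tolerance when comparing grid origins (mm)
ORIGIN_ATOL_MM = 1e-2

#: tolerance for off-diagonal affine entries when deciding axis alignment (mm)
_AFFINE_ATOL = 1e-4

METRICS_COLUMNS = [
    "patient_id",
    "reader_id",
    "filter_label",
    "mtv_cm3",
    "tlg",
    "dmax_cm",
    "n_lesions",
]


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


@dataclass
class SuvVolume:
    """A 3D grid of body-weight SUV values (dimensionless).

    Parameters
    ----------
    patient_id : str
        Opaque patient identifier.
    values : ndarray, shape (nx, ny, nz)
        Nonnegative, finite SUV values.
    spacing : array-like of 3 floats
        Voxel spacing per axis in mm; all components positive.
    origin : array-like of 3 floats
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    patient_id: str
    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D")
        if any(s < 1 for s in self.values.shape):
            raise ValueError(f"every axis must have length >= 1, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be nonnegative")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3 (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class SegmentationMask:
    """A binary lesion mask on the same lattice as its paired :class:`SuvVolume`."""

    patient_id: str
    reader_id: str
    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got {arr.ndim}D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0, 1}}, found {uniq[:5]}")
        self.values = arr.astype(np.uint8)
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())


def _grid_from_nifti(img: nib.Nifti1Image, path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (data, spacing, origin) from an axis-aligned NIfTI image.

    Axis permutations and flips are undone by reorienting the data array so
    the resulting affine is diagonal with positive spacing.
    """
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D volume, got {data.ndim}D data")
    ornt = nib.orientations.io_orientation(img.affine)
    data = nib.orientations.apply_orientation(data, ornt)
    affine = img.affine @ nib.orientations.inv_ornt_aff(ornt, img.shape)
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.any(np.abs(off_diag) > _AFFINE_ATOL):
        raise ValueError(
            f"{path}: only axis-aligned geometries (permutations/flips) are "
            "supported; affine has shear or rotation"
        )
    spacing = np.diag(rot).astype(float)
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    origin = affine[:3, 3].astype(float)
    return np.ascontiguousarray(data), spacing, origin


def load_suv_volume(path, patient_id: str | None = None) -> SuvVolume:
    """Load a 3D SUV volume from a NIfTI-1 file (.nii or .nii.gz).

    ``patient_id`` defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SUV volume not found: {path}")
    img = nib.load(path)
    data, spacing, origin = _grid_from_nifti(img, path)
    if patient_id is None:
        patient_id = path.name.removesuffix(".gz").removesuffix(".nii")
    return SuvVolume(patient_id=patient_id, values=np.asarray(data, dtype=float),
                     spacing=spacing, origin=origin)


def load_mask(path, reader_id: str, patient_id: str | None = None,
              binarize: bool = False) -> SegmentationMask:
    """Load a binary segmentation mask from a NIfTI-1 file.

    Values must be in {0, 1} unless ``binarize`` is set, in which case any
    value > 0.5 becomes foreground.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"segmentation mask not found: {path}")
    img = nib.load(path)
    data, spacing, origin = _grid_from_nifti(img, path)
    data = np.asarray(data, dtype=float)
    if binarize:
        values = (data > 0.5).astype(np.uint8)
    else:
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(
                f"{path}: mask contains values other than {{0, 1}} "
                f"({uniq[:5]}...); pass binarize=True to threshold at 0.5"
            )
        values = data.astype(np.uint8)
    if patient_id is None:
        patient_id = path.name.removesuffix(".gz").removesuffix(".nii")
    return SegmentationMask(patient_id=patient_id, reader_id=reader_id,
                            values=values, spacing=spacing, origin=origin)


def _diag_affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return affine


def write_suv_volume(vol: SuvVolume, path) -> None:
    """Write a SUV volume to NIfTI-1 as float64 (exact value round trip)."""
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64),
                          _diag_affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def write_mask(mask: SegmentationMask, path) -> None:
    """Write a binary mask to NIfTI-1 as uint8."""
    img = nib.Nifti1Image(np.asarray(mask.values, dtype=np.uint8),
                          _diag_affine(mask.spacing, mask.origin))
    nib.save(img, str(path))


def check_grid_compatible(vol: SuvVolume, mask: SegmentationMask) -> bool:
    """True iff shapes match and spacing/origin agree within tolerance.

    Spacing must agree within ``SPACING_ATOL_MM`` (1e-3 mm) per axis and the
    origins within ``ORIGIN_ATOL_MM`` (1e-2 mm).  Pure predicate; symmetric.
    """
    if vol.values.shape != mask.values.shape:
        return False
    if not np.all(np.abs(vol.spacing - mask.spacing) <= SPACING_ATOL_MM):
        return False
    return bool(np.all(np.abs(vol.origin - mask.origin) <= ORIGIN_ATOL_MM))


def write_metrics_table(records, path) -> None:
    """Write per-patient metric records to a CSV (RFC 4180, UTF-8, header row).

    One row per patient x reader x filter variant, columns
    ``patient_id, reader_id, filter_label, mtv_cm3, tlg, dmax_cm, n_lesions``.
    """
    records = list(records)
    if not records:
        raise ValueError("records must be nonempty")
    rows = [
        {
            "patient_id": r.patient_id,
            "reader_id": r.reader_id,
            "filter_label": r.filter_label,
            "mtv_cm3": r.mtv_cm3,
            "tlg": r.tlg,
            "dmax_cm": r.dmax_cm,
            "n_lesions": r.n_lesions,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=METRICS_COLUMNS).to_csv(path, index=False, encoding="utf-8")


def read_metrics_table(path):
    """Read a metrics CSV back into a list of ``PatientMetricSet`` records.

    Inverse of :func:`write_metrics_table` up to float round trip.
    """
    from .metrics import PatientMetricSet  # deferred: metrics imports this module

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metrics table not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "reader_id": str,
                                      "filter_label": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no records (empty file)") from None
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed metrics CSV, missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    return [
        PatientMetricSet(
            patient_id=str(row.patient_id),
            reader_id=str(row.reader_id),
            filter_label=str(row.filter_label),
            mtv_cm3=float(row.mtv_cm3),
            tlg=float(row.tlg),
            dmax_cm=float(row.dmax_cm),
            n_lesions=int(row.n_lesions),
        )
        for row in df.itertuples(index=False)
    ]
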