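"""Per-lesion and per-patient PET biomarkers: MTV, TLG and Dmax.

A "lesion" is a maximal connected component of the binary segmentation mask
under a configurable 3D connectivity (6, 18 or 26 neighbours).  From each
lesion we derive:

* its volume in cm^3 (voxel count x voxel volume),
* SUVmean, the arithmetic mean SUV over the lesion's voxels,
* TLG = SUVmean x volume (the glycolysis proxy, SUV.cm^3),
* the unweighted geometric centroid of its voxel centers in world mm.

Per patient and reader this yields

* MTV  -- metabolic tumour volume, the summed lesion volume (cm^3),
* TLG  -- summed per-lesion TLG,
* Dmax -- the Euclidean distance (cm) between the centroids of the two most
  widely separated lesions; defined as 0 when fewer than two lesions exist.

An optional volume filter drops lesions strictly smaller than a threshold
(3 cm^3 by default) before the patient-level metrics are computed, to probe
how inclusion of small lesions drives the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist

from .io import SegmentationMask, SuvVolume, check_grid_compatible

#: connectivity name -> rank passed to scipy's binary structure generator
_CONN_RANK = {6: 1, 18: 2, 26: 3}

DEFAULT_CONNECTIVITY = 26
DEFAULT_MIN_VOLUME_CM3 = 3.0


@dataclass
class Lesion:
    """One connected lesion with its derived quantities."""

    voxel_indices: np.ndarray  # (k, 3) int array, lexicographically sorted
    volume_cm3: float
    suv_mean: float
    tlg: float
    centroid_mm: np.ndarray  # (3,) world mm

    @property
    def n_voxels(self) -> int:
        return int(len(self.voxel_indices))


@dataclass
class PatientMetricSet:
    """Patient x reader x filter-variant summary metrics."""

    patient_id: str
    reader_id: str
    filter_label: str
    mtv_cm3: float
    tlg: float
    dmax_cm: float
    n_lesions: int

    def __post_init__(self):
        if self.mtv_cm3 < 0 or self.tlg < 0 or self.dmax_cm < 0:
            raise ValueError("metrics must be nonnegative")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be nonnegative")
        if self.n_lesions <= 1 and self.dmax_cm != 0:
            raise ValueError("dmax_cm must be 0 when n_lesions <= 1")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONN_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONN_RANK)}, "
                         f"got {connectivity}")
    return ndimage.generate_binary_structure(3, _CONN_RANK[connectivity])


def label_lesions(mask, connectivity: int = DEFAULT_CONNECTIVITY) -> list[np.ndarray]:
    """Partition foreground voxels into maximal connected components.

    Parameters
    ----------
    mask : SegmentationMask or binary ndarray
    connectivity : {6, 18, 26}
        Face / face+edge / face+edge+vertex adjacency.

    Returns
    -------
    list of (k, 3) int arrays, one per component, each lexicographically
    sorted; components ordered by their lexicographically smallest voxel.
    An empty mask yields an empty list.
    """
    values = mask.values if isinstance(mask, SegmentationMask) else np.asarray(mask)
    labeled, n = ndimage.label(values, structure=_structure(connectivity))
    if n == 0:
        return []
    coords = np.argwhere(labeled)          # C-order == lexicographic order
    labels_at = labeled[tuple(coords.T)]
    # order components by first appearance in lexicographic scan
    _, first_pos = np.unique(labels_at, return_index=True)
    order = labels_at[np.sort(first_pos)]
    return [coords[labels_at == lbl] for lbl in order]


def lesion_from_component(component, vol: SuvVolume,
                          spacing=None, origin=None) -> Lesion:
    """Build a :class:`Lesion` from a voxel-index set and the SUV volume.

    ``spacing``/``origin`` default to the volume's grid; pass the mask's
    geometry to use it instead (the two must be grid-compatible).
    """
    idx = np.asarray(list(component) if not isinstance(component, np.ndarray)
                     else component, dtype=int)
    if idx.ndim != 2 or idx.shape[1] != 3 or len(idx) == 0:
        raise ValueError("component must be a nonempty set of 3D voxel indices")
    shape = np.asarray(vol.values.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise IndexError(f"component references voxels outside the grid {tuple(shape)}")
    spacing = np.asarray(vol.spacing if spacing is None else spacing, dtype=float)
    origin = np.asarray(vol.origin if origin is None else origin, dtype=float)

    volume_cm3 = len(idx) * float(np.prod(spacing)) / 1000.0
    suv_mean = float(vol.values[tuple(idx.T)].mean())
    centroid_mm = origin + idx.mean(axis=0) * spacing
    return Lesion(
        voxel_indices=idx[np.lexsort(idx.T[::-1])],
        volume_cm3=volume_cm3,
        suv_mean=suv_mean,
        tlg=suv_mean * volume_cm3,
        centroid_mm=centroid_mm,
    )


def compute_dmax(lesions) -> float:
    """Dissemination distance: max pairwise centroid distance, in cm.

    Returns 0.0 when fewer than two lesions are present.
    """
    lesions = list(lesions)
    if len(lesions) < 2:
        return 0.0
    centroids = np.vstack([l.centroid_mm for l in lesions])
    return float(pdist(centroids).max()) / 10.0  # mm -> cm


def apply_volume_filter(lesions, min_volume_cm3: float = DEFAULT_MIN_VOLUME_CM3):
    """Drop lesions strictly smaller than ``min_volume_cm3``; order preserved.

    A lesion of exactly the threshold volume is retained ("smaller than"
    read strictly).
    """
    if min_volume_cm3 < 0:
        raise ValueError("min_volume_cm3 must be nonnegative")
    return [l for l in lesions if l.volume_cm3 >= min_volume_cm3]


def filter_label_for(min_volume_cm3: float | None) -> str:
    """Canonical filter-variant label: 'all' or e.g. 'ge3cm3'."""
    if min_volume_cm3 is None:
        return "all"
    return f"ge{min_volume_cm3:g}cm3"


def compute_patient_metrics(vol: SuvVolume, mask: SegmentationMask,
                            connectivity: int = DEFAULT_CONNECTIVITY,
                            min_volume_cm3: float | None = None) -> PatientMetricSet:
    """MTV, TLG, Dmax and lesion count for one patient x reader.

    When ``min_volume_cm3`` is given, lesions below it are excluded before
    any patient-level metric is computed (so Dmax too is taken over the
    retained lesions only) and the record is labelled accordingly.
    """
    if not check_grid_compatible(vol, mask):
        raise ValueError(
            f"SUV volume and mask for patient {mask.patient_id!r} "
            f"(reader {mask.reader_id!r}) are not grid-compatible"
        )
    components = label_lesions(mask, connectivity=connectivity)
    lesions = [lesion_from_component(c, vol, mask.spacing, mask.origin)
               for c in components]
    if min_volume_cm3 is not None:
        lesions = apply_volume_filter(lesions, min_volume_cm3)
    return PatientMetricSet(
        patient_id=mask.patient_id,
        reader_id=mask.reader_id,
        filter_label=filter_label_for(min_volume_cm3),
        mtv_cm3=float(sum(l.volume_cm3 for l in lesions)),
        tlg=float(sum(l.tlg for l in lesions)),
        dmax_cm=compute_dmax(lesions),
        n_lesions=len(lesions),
    )
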