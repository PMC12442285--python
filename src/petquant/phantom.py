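"""Synthetic two-reader phantom cohorts for exercising the full pipeline.

Each simulated patient is a whole-body-scale voxel grid containing a set of
non-touching spherical FDG-avid lesions on a uniform background.  Inside a
lesion the SUV falls off radially from a per-lesion peak down to the
background at the boundary.  Two "readers" then segment the patient by
perturbing the ground-truth mask independently:

* boundary jitter -- each lesion is dilated or eroded by a per-lesion
  signed margin drawn uniformly from [-boundary_jitter_mm, +boundary_jitter_mm],
  rounded toward zero to whole structuring-element steps (one step = the
  smallest voxel edge);
* small-lesion omission -- a lesion whose volume is below
  ``omit_volume_threshold_cm3`` is dropped entirely with probability
  ``small_lesion_omit_prob``.

The omission channel is the mechanism by which reader disagreement on small,
spatially separated lesions perturbs the dissemination distance Dmax far
more than it perturbs total volume (MTV) or glycolysis (TLG).

All randomness derives from a master seed through named per-patient
substreams (truth, reader A, reader B), so identical configurations produce
identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import SegmentationMask, SuvVolume, write_mask, write_suv_volume
from .metrics import compute_patient_metrics, label_lesions

_STREAM_TRUTH, _STREAM_READER_A, _STREAM_READER_B = 0, 1, 2

#: clearance (in voxels of the largest spacing) added to the pairwise
#: separation constraint so true lesions never touch under any connectivity
_SEPARATION_VOXELS = 2


@dataclass
class PhantomConfig:
    """Cohort-level simulation parameters.

    Defaults describe a whole-body FDG PET at typical reconstruction
    resolution (4 mm isotropic voxels, 25.6 x 25.6 x 64 cm field of view)
    with a handful of lesions per patient spanning sub-centimetre nodes to
    bulky masses, chosen so cohort medians land in the range reported for
    untreated aggressive lymphoma (MTV of order hundreds of cm^3, TLG of
    order thousands, Dmax of order tens of cm).
    """

    n_patients: int = 117
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 160)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    lesion_count_mean: float = 6.0
    radius_range_mm: tuple[float, float] = (5.0, 35.0)
    suv_peak_range: tuple[float, float] = (8.0, 25.0)
    background_suv: float = 1.0
    boundary_jitter_mm: float = 6.0
    small_lesion_omit_prob: float = 0.3
    omit_volume_threshold_cm3: float = 3.0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be positive, got {self.n_patients}")
        if not (0 <= int(self.seed) < 2 ** 31):
            raise ValueError(f"seed must be a nonnegative 31-bit integer, got {self.seed}")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive integers, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")
        if self.lesion_count_mean <= 0:
            raise ValueError(f"lesion_count_mean must be positive, got {self.lesion_count_mean}")
        for name in ("radius_range_mm", "suv_peak_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high, got {(lo, hi)}")
        if self.suv_peak_range[0] <= self.background_suv:
            raise ValueError("suv_peak_range low must exceed background_suv")
        if self.background_suv < 0:
            raise ValueError(f"background_suv must be nonnegative, got {self.background_suv}")
        if self.boundary_jitter_mm < 0:
            raise ValueError(f"boundary_jitter_mm must be nonnegative, got {self.boundary_jitter_mm}")
        if not (0 <= self.small_lesion_omit_prob <= 1):
            raise ValueError("small_lesion_omit_prob must be a probability in [0, 1], "
                             f"got {self.small_lesion_omit_prob}")
        if self.omit_volume_threshold_cm3 <= 0:
            raise ValueError("omit_volume_threshold_cm3 must be positive, "
                             f"got {self.omit_volume_threshold_cm3}")
        extent = np.array(self.grid_shape) * np.array(self.spacing_mm)
        needed = 2 * (self.radius_range_mm[1] + self.boundary_jitter_mm
                      + max(self.spacing_mm))
        if np.any(extent < needed):
            raise ValueError(
                f"grid extent {tuple(extent)} mm cannot contain the largest "
                f"lesion radius plus jitter (needs >= {needed:.1f} mm per axis)"
            )


@dataclass
class TruthLesion:
    """Ground-truth sphere parameters (world mm, origin at voxel (0,0,0))."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    suv_peak: float


def _rng(config: PhantomConfig, patient_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(patient_index), int(stream)])
    )


def generate_truth(config: PhantomConfig) -> list[list[TruthLesion]]:
    """Draw ground-truth lesion parameters for every patient.

    Lesion count per patient is max(1, Poisson(lesion_count_mean)); radii
    are log-uniform in their range (lymphoma burden is right-skewed: many
    small nodes, an occasional bulky mass), SUV peaks are uniform in
    theirs; centers are uniform inside
    the grid subject to full containment (with jitter clearance) and a
    pairwise center separation of at least the sum of radii plus two voxels
    so true lesions can never merge.
    """
    extent = np.array(config.grid_shape) * np.array(config.spacing_mm)
    max_sp = max(config.spacing_mm)
    cohort = []
    for i in range(config.n_patients):
        rng = _rng(config, i, _STREAM_TRUTH)
        n_lesions = max(1, int(rng.poisson(config.lesion_count_mean)))
        r_lo, r_hi = config.radius_range_mm
        radii = np.exp(rng.uniform(np.log(r_lo), np.log(r_hi), size=n_lesions))
        peaks = rng.uniform(*config.suv_peak_range, size=n_lesions)
        placed: list[TruthLesion] = []
        for r, peak in zip(radii, peaks):
            margin = r + config.boundary_jitter_mm + max_sp
            lo, hi = margin, extent - margin
            for _ in range(500):
                c = rng.uniform(lo, hi)
                ok = all(
                    np.linalg.norm(c - np.asarray(p.center_mm))
                    >= r + p.radius_mm + _SEPARATION_VOXELS * max_sp
                    for p in placed
                )
                if ok:
                    placed.append(TruthLesion(tuple(float(x) for x in c),
                                              float(r), float(peak)))
                    break
            else:
                raise RuntimeError(
                    f"could not place lesion (radius {r:.1f} mm) for patient "
                    f"{i} after 500 attempts; grid {config.grid_shape} at "
                    f"{config.spacing_mm} mm is too congested for "
                    f"lesion_count_mean={config.lesion_count_mean}"
                )
        cohort.append(placed)
    return cohort


def rasterize_patient(lesions: list[TruthLesion], config: PhantomConfig,
                      patient_id: str) -> tuple[SuvVolume, SegmentationMask]:
    """Render one patient's SUV volume and ground-truth mask.

    A voxel is foreground iff its center lies within some lesion sphere.
    Inside lesion i the SUV is background + (peak_i - background) *
    (1 - (d/r)^2), a parabolic falloff reaching the background exactly at
    the boundary; outside all lesions the SUV is the background.
    """
    shape = config.grid_shape
    sp = np.asarray(config.spacing_mm)
    suv = np.full(shape, float(config.background_suv))
    mask = np.zeros(shape, dtype=bool)
    for les in lesions:
        c = np.asarray(les.center_mm)
        r = les.radius_mm
        lo = np.maximum(np.floor((c - r) / sp).astype(int), 0)
        hi = np.minimum(np.ceil((c + r) / sp).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ix, iy, iz = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        d2 = ((ix * sp[0] - c[0]) ** 2 + (iy * sp[1] - c[1]) ** 2
              + (iz * sp[2] - c[2]) ** 2)
        inside = d2 <= r * r + 1e-9
        sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        mask[sub] |= inside
        profile = (config.background_suv
                   + (les.suv_peak - config.background_suv)
                   * (1.0 - d2 / (r * r)))
        suv[sub] = np.where(inside, np.maximum(profile, config.background_suv),
                            suv[sub])
    vol = SuvVolume(patient_id=patient_id, values=suv,
                    spacing=sp, origin=np.zeros(3))
    true_mask = SegmentationMask(patient_id=patient_id, reader_id="truth",
                                 values=mask.astype(np.uint8),
                                 spacing=sp, origin=np.zeros(3))
    return vol, true_mask


def _ball_element(radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Isotropic (in physical mm) structuring element on the voxel lattice."""
    n = np.floor(radius_mm / spacing).astype(int)
    ox, oy, oz = np.ogrid[-n[0]:n[0] + 1, -n[1]:n[1] + 1, -n[2]:n[2] + 1]
    d2 = (ox * spacing[0]) ** 2 + (oy * spacing[1]) ** 2 + (oz * spacing[2]) ** 2
    return d2 <= radius_mm ** 2 + 1e-9


def perturb_reading(true_mask: SegmentationMask, config: PhantomConfig,
                    rng: np.random.Generator,
                    reader_id: str) -> SegmentationMask:
    """Produce one reader's segmentation from the ground-truth mask.

    Per lesion (26-connected component of the truth), independently:
    with probability ``small_lesion_omit_prob`` — and only if the lesion's
    volume is below ``omit_volume_threshold_cm3`` — drop it; otherwise
    dilate (positive) or erode (negative) it by a signed margin uniform in
    [-boundary_jitter_mm, +boundary_jitter_mm], truncated toward zero to
    whole structuring-element steps of the smallest voxel edge.  Zero
    jitter and zero omission probability reproduce the truth exactly.

    The random draws (one omission uniform and one margin per lesion) are
    consumed for every lesion regardless of the decision taken, so cohorts
    that differ only in the perturbation probabilities stay voxel-aligned
    at the same seed.
    """
    sp = np.asarray(true_mask.spacing)
    step_mm = float(sp.min())
    voxvol_cm3 = float(np.prod(sp)) / 1000.0
    shape = true_mask.values.shape
    out = np.zeros(shape, dtype=bool)
    for comp in label_lesions(true_mask.values, connectivity=26):
        u_omit = rng.random()
        margin = rng.uniform(-config.boundary_jitter_mm, config.boundary_jitter_mm)
        volume = len(comp) * voxvol_cm3
        if (volume < config.omit_volume_threshold_cm3
                and u_omit < config.small_lesion_omit_prob):
            continue
        steps = int(margin / step_mm)  # int() truncates toward zero
        if steps == 0:
            out[tuple(comp.T)] = True
            continue
        pad = abs(steps) + 1
        lo = np.maximum(comp.min(axis=0) - pad, 0)
        hi = np.minimum(comp.max(axis=0) + pad + 1, shape)
        sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        local = np.zeros(tuple(hi - lo), dtype=bool)
        local[tuple((comp - lo).T)] = True
        selem = _ball_element(abs(steps) * step_mm, sp)
        if steps > 0:
            local = ndimage.binary_dilation(local, structure=selem)
        else:
            local = ndimage.binary_erosion(local, structure=selem)
        out[sub] |= local
    return SegmentationMask(patient_id=true_mask.patient_id, reader_id=reader_id,
                            values=out.astype(np.uint8),
                            spacing=true_mask.spacing, origin=true_mask.origin)


def simulate_patient(config: PhantomConfig, patient_index: int,
                     truth: list[TruthLesion] | None = None):
    """Truth + rasterization + both reader perturbations for one patient.

    Returns ``(vol, true_mask, mask_a, mask_b, truth_lesions)``.
    """
    if truth is None:
        truth = generate_truth(
            dataclasses.replace(config, n_patients=patient_index + 1)
        )[patient_index]
    pid = f"P{patient_index:03d}"
    vol, true_mask = rasterize_patient(truth, config, pid)
    mask_a = perturb_reading(true_mask, config,
                             _rng(config, patient_index, _STREAM_READER_A), "A")
    mask_b = perturb_reading(true_mask, config,
                             _rng(config, patient_index, _STREAM_READER_B), "B")
    return vol, true_mask, mask_a, mask_b, truth


def generate_cohort(config: PhantomConfig, out_dir,
                    connectivity: int = 26,
                    compress: bool = True) -> dict:
    """Write a full phantom cohort to disk and return its manifest.

    Per patient this emits the SUV volume and the two reader masks as
    NIfTI-1 files, plus a single ``manifest.json`` recording the config,
    the file paths, the ground-truth sphere parameters and the expected
    per-reader metrics.  Expected metrics are computed by running the
    lesion-metrics pipeline on the realized (perturbed, rasterized) masks,
    for both the unfiltered and the >= 3 cm^3-filtered variants, so the
    manifest is the oracle for I/O round trips rather than for the math.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    truth_all = generate_truth(config)
    patients = []
    for i in range(config.n_patients):
        vol, true_mask, mask_a, mask_b, truth = simulate_patient(
            config, i, truth=truth_all[i])
        pid = vol.patient_id
        paths = {
            "suv": f"{pid}_suv{ext}",
            "mask_a": f"{pid}_mask_A{ext}",
            "mask_b": f"{pid}_mask_B{ext}",
        }
        try:
            write_suv_volume(vol, out_dir / paths["suv"])
            write_mask(mask_a, out_dir / paths["mask_a"])
            write_mask(mask_b, out_dir / paths["mask_b"])
        except OSError as exc:
            raise OSError(f"failed writing phantom files for {pid} under "
                          f"{out_dir}: {exc}") from exc
        expected = []
        for mask in (mask_a, mask_b):
            for min_vol in (None, 3.0):
                rec = compute_patient_metrics(vol, mask, connectivity=connectivity,
                                              min_volume_cm3=min_vol)
                expected.append(dataclasses.asdict(rec))
        patients.append({
            "patient_id": pid,
            "files": paths,
            "truth_lesions": [asdict(t) for t in truth],
            "expected_metrics": expected,
        })
    manifest = {
        "config": asdict(config),
        "connectivity": connectivity,
        "patients": patients,
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
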