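"""Study image containers, NIfTI I/O, and reference-tissue normalization.

A study is a set of co-registered 3D volumes (five MR contrasts), an
integer label map of the lesion compartments, and an intracranial-volume
(ICV) mask. Registration and skull stripping are assumed to have happened
upstream; this module validates their postcondition (identical grids) and
performs the min/max intensity normalization used before feature
extraction, with normal-appearing tissue (ICV voxels outside every
segmented alteration) as the reference region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .constants import LABEL_CODES, SEQUENCES, VALID_LABELS

logger = logging.getLogger(__name__)

AFFINE_TOL = 1e-3


class StudyValidationError(ValueError):
    """Raised when a study's volumes, labels or mask are inconsistent."""


@dataclass
class ImageVolume:
    """One 3D scalar image of a known MR contrast.

    Parameters
    ----------
    data : 3D float array.
    voxel_size_mm : per-axis voxel edge length in millimetres.
    sequence : one of ``SEQUENCES``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    sequence: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise StudyValidationError(f"{self.sequence}: expected a 3D volume, got {self.data.ndim}D")
        if self.sequence not in SEQUENCES:
            raise StudyValidationError(f"unknown sequence {self.sequence!r}; expected one of {SEQUENCES}")
        if not np.all(np.isfinite(self.data)):
            raise StudyValidationError(f"{self.sequence}: non-finite voxel values present")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise StudyValidationError(f"{self.sequence}: voxel sizes must be positive, got {self.voxel_size_mm}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class LabelMap:
    """Integer lesion segmentation on the study grid.

    Coding: 0 background/normal-appearing, 1 necrosis, 2 CET, 3 nCET,
    4 edema, 5 hemorrhage (never used by features).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise StudyValidationError("label map contains non-integer values")
            self.labels = rounded.astype(np.int16)
        present = set(np.unique(self.labels).tolist())
        if not present <= VALID_LABELS:
            raise StudyValidationError(f"label map contains invalid codes {sorted(present - VALID_LABELS)}")

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == LABEL_CODES[tissue]

    @property
    def lesion_mask(self) -> np.ndarray:
        """All segmented alterations, hemorrhage included."""
        return self.labels > 0


@dataclass
class MRIStudy:
    """One subject's co-registered volumes, label map and ICV mask."""

    subject_id: str
    volumes: Mapping[str, ImageVolume]
    label_map: LabelMap
    icv_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        missing = [s for s in SEQUENCES if s not in self.volumes]
        if missing:
            raise StudyValidationError(f"study {self.subject_id}: missing sequence(s) {missing}")
        self.icv_mask = np.asarray(self.icv_mask).astype(bool)
        shape = self.icv_mask.shape
        for seq in SEQUENCES:
            vol = self.volumes[seq]
            if vol.data.shape != shape:
                raise StudyValidationError(
                    f"study {self.subject_id}: {seq} grid {vol.data.shape} does not match mask grid {shape}"
                )
            if not np.allclose(vol.voxel_size_mm, self.voxel_size_mm, atol=AFFINE_TOL):
                raise StudyValidationError(
                    f"study {self.subject_id}: {seq} voxel size {vol.voxel_size_mm} "
                    f"differs from study voxel size {self.voxel_size_mm}"
                )
        if self.label_map.labels.shape != shape:
            raise StudyValidationError(
                f"study {self.subject_id}: label grid {self.label_map.labels.shape} "
                f"does not match volume grid {shape}"
            )
        outside = self.label_map.lesion_mask & ~self.icv_mask
        if outside.any():
            raise StudyValidationError(
                f"study {self.subject_id}: {int(outside.sum())} lesion voxels fall outside the ICV mask"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.icv_mask.shape

    def normal_appearing_mask(self) -> np.ndarray:
        """Reference region: intracranial voxels outside every alteration."""
        return self.icv_mask & (self.label_map.labels == 0)


def _load_nifti(path: Path) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine), zooms


def load_study(
    subject_id: str,
    sequence_paths: Mapping[str, str | Path],
    label_path: str | Path,
    mask_path: str | Path,
    affine_tol: float = AFFINE_TOL,
) -> MRIStudy:
    """Load and validate one study from NIfTI files.

    Raises ``StudyValidationError`` naming any absent sequence, and on any
    grid-shape or affine mismatch across the files (no silent resampling).
    """
    missing = [s for s in SEQUENCES if s not in sequence_paths]
    if missing:
        raise StudyValidationError(f"study {subject_id}: no file provided for sequence(s) {missing}")
    for name, p in {**dict(sequence_paths), "labels": label_path, "mask": mask_path}.items():
        if not Path(p).exists():
            raise StudyValidationError(f"study {subject_id}: file for {name} not found: {p}")

    volumes: dict[str, ImageVolume] = {}
    ref_affine = None
    ref_zooms = None
    for seq in SEQUENCES:
        data, affine, zooms = _load_nifti(Path(sequence_paths[seq]))
        if not np.all(np.isfinite(data)):
            raise StudyValidationError(f"study {subject_id}: {sequence_paths[seq]} contains non-finite values")
        if ref_affine is None:
            ref_affine, ref_zooms = affine, zooms
        elif not np.allclose(affine, ref_affine, atol=affine_tol):
            raise StudyValidationError(f"study {subject_id}: affine of {seq} disagrees beyond tol={affine_tol}")
        volumes[seq] = ImageVolume(data=data, voxel_size_mm=zooms, sequence=seq)

    labels, laffine, _ = _load_nifti(Path(label_path))
    mask, maffine, _ = _load_nifti(Path(mask_path))
    for name, aff in (("labels", laffine), ("mask", maffine)):
        if not np.allclose(aff, ref_affine, atol=affine_tol):
            raise StudyValidationError(f"study {subject_id}: affine of {name} disagrees beyond tol={affine_tol}")
    return MRIStudy(
        subject_id=subject_id,
        volumes=volumes,
        label_map=LabelMap(labels=labels),
        icv_mask=mask > 0.5,
        voxel_size_mm=ref_zooms,
    )


def save_study(study: MRIStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a study as uncompressed-grid NIfTI (.nii.gz) files.

    Returns the mapping of logical name (sequence, ``labels``, ``mask``)
    to written path. Voxel data round-trips bit-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(study.voxel_size_mm) + [1.0])
    paths: dict[str, Path] = {}
    for seq in SEQUENCES:
        p = out / f"{seq}.nii.gz"
        nib.save(nib.Nifti1Image(study.volumes[seq].data, affine), str(p))
        paths[seq] = p
    p = out / "labels.nii.gz"
    nib.save(nib.Nifti1Image(study.label_map.labels.astype(np.int16), affine), str(p))
    paths["labels"] = p
    p = out / "mask.nii.gz"
    nib.save(nib.Nifti1Image(study.icv_mask.astype(np.uint8), affine), str(p))
    paths["mask"] = p
    return paths


def normalize_minmax(volume: ImageVolume, label_map: LabelMap, icv_mask: np.ndarray) -> ImageVolume:
    """Min/max-normalize against normal-appearing tissue.

    The affine map ``(x - min_ref) / (max_ref - min_ref)`` is applied to the
    whole volume, with the reference extrema taken over intracranial voxels
    carrying label 0. Reference voxels land in [0, 1]; lesion voxels may
    fall outside and are deliberately not clipped (the fraction outside is
    logged at DEBUG level).
    """
    icv_mask = np.asarray(icv_mask).astype(bool)
    ref = icv_mask & (label_map.labels == 0)
    if not ref.any():
        raise StudyValidationError(f"{volume.sequence}: empty normal-appearing reference region")
    ref_vals = volume.data[ref]
    lo, hi = float(ref_vals.min()), float(ref_vals.max())
    if hi == lo:
        raise StudyValidationError(f"{volume.sequence}: degenerate reference region (constant intensity {lo})")
    out = (volume.data - lo) / (hi - lo)
    frac_outside = float(np.mean((out[icv_mask] < 0) | (out[icv_mask] > 1)))
    logger.debug("%s: %.3f%% of intracranial voxels outside [0,1] after normalization", volume.sequence, 100 * frac_outside)
    return replace(volume, data=out)
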