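"""The fixed 68-feature radiomic schema and its extraction.

Per lesion compartment (necrosis, CET, nCET, edema) the schema holds two
morphological features (ROI volume in mm³ and ROI volume normalized to the
intracranial volume) plus, for each of the five images (T1w, GdT1w, T2w,
FLAIR, ADC), the mean, the standard deviation and the fractality of the
normalized intensity: 17 features per tissue, 68 in total. Missing ROIs
produce missing cells (never zeros).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import SEQUENCES, TISSUES
from .fractal import DEFAULT_N_THRESHOLDS, fractality
from .imaging import ImageVolume, MRIStudy, normalize_minmax

MORPH_KINDS = ("volume", "volume_norm")
INTENSITY_KINDS = ("avg", "std", "fract")


@dataclass(frozen=True)
class FeatureKey:
    """Identifies one cell of the schema: (tissue, image, kind).

    ``image`` is ``"none"`` exactly for the two morphological kinds.
    """

    tissue: str
    image: str
    kind: str

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.kind in MORPH_KINDS:
            if self.image != "none":
                raise ValueError(f"morphological kind {self.kind!r} requires image='none'")
        elif self.kind in INTENSITY_KINDS:
            if self.image not in SEQUENCES:
                raise ValueError(f"kind {self.kind!r} requires a sequence image, got {self.image!r}")
        else:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def name(self) -> str:
        return f"{self.tissue}__{self.image}__{self.kind}"

    @classmethod
    def from_name(cls, name: str) -> "FeatureKey":
        tissue, image, kind = name.split("__")
        return cls(tissue=tissue, image=image, kind=kind)


def feature_schema(tissues: tuple[str, ...] = TISSUES) -> list[FeatureKey]:
    """The canonical ordered key list: 17 per tissue, 68 overall."""
    keys: list[FeatureKey] = []
    for tissue in tissues:
        for kind in MORPH_KINDS:
            keys.append(FeatureKey(tissue, "none", kind))
        for image in SEQUENCES:
            for kind in INTENSITY_KINDS:
                keys.append(FeatureKey(tissue, image, kind))
    return keys


def feature_names(tissues: tuple[str, ...] = TISSUES) -> list[str]:
    return [k.name for k in feature_schema(tissues)]


def roi_volume(study: MRIStudy, tissue: str) -> tuple[float, float]:
    """ROI volume in mm³ and as a fraction of the intracranial volume.

    Returns ``(nan, nan)`` for an empty ROI; an empty ICV mask is an error.
    """
    icv_count = int(study.icv_mask.sum())
    if icv_count == 0:
        raise ValueError(f"study {study.subject_id}: empty ICV mask")
    count = int(study.label_map.mask(tissue).sum())
    if count == 0:
        return float("nan"), float("nan")
    voxel_vol = float(np.prod(study.voxel_size_mm))
    return count * voxel_vol, count / icv_count


def roi_intensity_stats(volume: ImageVolume | np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Mean and sample standard deviation (n−1) over masked voxels.

    An empty mask yields ``(nan, nan)``; a single-voxel ROI has a defined
    mean but a missing SD.
    """
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    vals = data[np.asarray(mask).astype(bool)]
    if vals.size == 0:
        return float("nan"), float("nan")
    avg = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return avg, sd


def extract_features(
    study: MRIStudy,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    box_sizes: list[int] | None = None,
) -> pd.Series:
    """Compute one subject's 68-feature row.

    Volumes are min/max-normalized against normal-appearing tissue before
    any intensity or texture feature is computed. Hemorrhage voxels
    (label 5) contribute to no feature. Empty ROIs yield NaN cells.
    """
    normalized = {
        seq: normalize_minmax(study.volumes[seq], study.label_map, study.icv_mask) for seq in SEQUENCES
    }
    row: dict[str, float] = {}
    for tissue in TISSUES:
        mask = study.label_map.mask(tissue)
        vol, vol_norm = roi_volume(study, tissue)
        row[FeatureKey(tissue, "none", "volume").name] = vol
        row[FeatureKey(tissue, "none", "volume_norm").name] = vol_norm
        for seq in SEQUENCES:
            data = normalized[seq].data
            avg, sd = roi_intensity_stats(data, mask)
            row[FeatureKey(tissue, seq, "avg").name] = avg
            row[FeatureKey(tissue, seq, "std").name] = sd
            row[FeatureKey(tissue, seq, "fract").name] = (
                fractality(data, mask, n_thresholds=n_thresholds, box_sizes=box_sizes)
                if mask.any()
                else float("nan")
            )
    return pd.Series(row, name=study.subject_id).reindex(feature_names())


def extract_feature_table(
    studies: list[MRIStudy],
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    box_sizes: list[int] | None = None,
) -> pd.DataFrame:
    """Stack per-study rows into a subjects × 68 FeatureTable."""
    rows = [extract_features(s, n_thresholds=n_thresholds, box_sizes=box_sizes) for s in studies]
    return pd.DataFrame(rows)


def tissue_block(table: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """The 17-column slice of a FeatureTable belonging to one tissue."""
    return table[[k.name for k in feature_schema((tissue,))]]
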