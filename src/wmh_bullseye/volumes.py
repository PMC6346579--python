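"""In-memory containers for the 3D volumes the pipeline exchanges.

All volumes are plain numpy grids with an isotropic-or-not voxel size in mm
and are (de)serialized as NIfTI-1 through nibabel, with a diagonal affine
built from the voxel size.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

# Label scheme of the anatomical label volume.
LABEL_BACKGROUND = 0
LABEL_CORTEX = 1
LABEL_VENTRICLES = 2
LABEL_BASAL_GANGLIA = 3
# Lobar white matter: frontal/parietal/temporal/occipital, left/right.
LOBAR_LABELS = {
    11: "FL", 12: "FR",
    13: "PL", 14: "PR",
    15: "TL", 16: "TR",
    17: "OL", 18: "OR",
}
ALL_LABELS = (
    {LABEL_BACKGROUND, LABEL_CORTEX, LABEL_VENTRICLES, LABEL_BASAL_GANGLIA}
    | set(LOBAR_LABELS)
)


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class _Volume:
    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be a 3D grid")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data), _affine(self.voxel_size))
        nib.save(img, str(path))

    @classmethod
    def load(cls, path):
        img = nib.load(str(path))
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj), vox)


@dataclass
class LabelVolume(_Volume):
    """Anatomical label grid: cortex sheet, ventricles/CSF, lobar WM, basal ganglia."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.int16, copy=False)
        unknown = set(np.unique(self.data)) - ALL_LABELS
        if unknown:
            raise ValueError(f"unknown label codes: {sorted(unknown)}")

    @property
    def wm_mask(self) -> np.ndarray:
        """White matter + basal ganglia: the voxels that receive a bullseye code."""
        return (self.data == LABEL_BASAL_GANGLIA) | (self.data >= 11)


@dataclass
class LesionProbabilityVolume(_Volume):
    """Voxelwise WMH probability in [0, 1], aligned to a LabelVolume."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.float32, copy=False)
        if np.nanmin(self.data) < 0 or np.nanmax(self.data) > 1:
            raise ValueError("lesion probabilities must lie in [0, 1]")


@dataclass
class DepthVolume(_Volume):
    """Normalized ventricle-to-cortex depth f in [0, 1]; NaN outside WM+BG."""


@dataclass
class ParcellationVolume(_Volume):
    """Bullseye region codes 1..36 on WM+BG voxels, 0 elsewhere."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.int16, copy=False)
        if self.data.min() < 0 or self.data.max() > 36:
            raise ValueError("region codes must lie in 0..36")


def check_aligned(a: _Volume, b: _Volume) -> None:
    if a.shape != b.shape or not np.allclose(a.voxel_size, b.voxel_size):
        raise ValueError("volumes are not aligned (shape/voxel size mismatch)")
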