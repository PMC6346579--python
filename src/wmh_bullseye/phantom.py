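"""Stylized concentric brain phantom and lesion planting.

The phantom is topology, not anatomy: a central ventricular ball, a white
matter shell split into eight angular lobar wedges (left/right x frontal /
parietal / temporal / occipital) plus a basal-ganglia cone rooted at the
ventricular surface, all wrapped in a thin cortical sheet.  This provides
exactly what the bullseye construction needs - a ventricular surface, a
cortical sheet, and nine labelled segments that each span the full
ventricle-to-cortex depth range.

Lesions are planted as probability mass: a participant's lesion *fraction
of intracranial volume* is converted into probability units and scattered
over WM voxels sampled proportionally to the 36 per-region spatial weights
(uniformly within a region).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import GeneratorParams
from .parcellation import build_parcellation
from .volumes import (LABEL_BASAL_GANGLIA, LABEL_CORTEX, LABEL_VENTRICLES,
                      LabelVolume, LesionProbabilityVolume,
                      ParcellationVolume)

# radii as fractions of the half-extent of the grid (mm)
_R_VENT = 0.15
_R_WM = 0.80
_CORTEX_VOXELS = 2.0
_BG_HALF_ANGLE_DEG = 25.0


def build_label_volume(shape: tuple[int, int, int] = (64, 64, 64),
                       voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       ) -> LabelVolume:
    """Deterministic concentric phantom on the given grid."""
    shape = tuple(int(s) for s in shape)
    voxel_size = tuple(float(v) for v in voxel_size)
    if min(shape) < 24:
        raise ValueError("grid too small to host disjoint ventricle/WM/cortex "
                         "shells (need at least 24 voxels per axis)")
    half_extent = min(s * v for s, v in zip(shape, voxel_size)) / 2.0
    r_vent = _R_VENT * half_extent
    r_wm = _R_WM * half_extent
    r_cortex = r_wm + _CORTEX_VOXELS * max(voxel_size)

    idx = np.indices(shape, dtype=float)
    x = (idx[0] - (shape[0] - 1) / 2.0) * voxel_size[0]
    y = (idx[1] - (shape[1] - 1) / 2.0) * voxel_size[1]
    z = (idx[2] - (shape[2] - 1) / 2.0) * voxel_size[2]
    r = np.sqrt(x * x + y * y + z * z)

    labels = np.zeros(shape, dtype=np.int16)
    labels[r <= r_vent] = LABEL_VENTRICLES
    wm = (r > r_vent) & (r <= r_wm)
    labels[(r > r_wm) & (r <= r_cortex)] = LABEL_CORTEX

    # eight lobar wedges: hemisphere by x sign, lobe by the angle in (y, z)
    theta = np.arctan2(z, y)  # frontal +y, parietal +z, occipital -y, temporal -z
    lobe = np.full(shape, 17, dtype=np.int16)                    # occipital
    lobe[(theta >= -np.pi / 4) & (theta < np.pi / 4)] = 11       # frontal
    lobe[(theta >= np.pi / 4) & (theta < 3 * np.pi / 4)] = 13    # parietal
    lobe[(theta >= -3 * np.pi / 4) & (theta < -np.pi / 4)] = 15  # temporal
    lobe = lobe + (x >= 0).astype(np.int16)                      # right = +1
    labels[wm] = lobe[wm]

    # basal-ganglia cone around the inferior (-z) axis, full shell depth
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_bg = np.where(r > 0, -z / np.maximum(r, 1e-9), 0.0)
    bg = wm & (cos_bg > np.cos(np.deg2rad(_BG_HALF_ANGLE_DEG)))
    labels[bg] = LABEL_BASAL_GANGLIA

    vol = LabelVolume(labels, voxel_size)
    for code in (LABEL_CORTEX, LABEL_VENTRICLES, LABEL_BASAL_GANGLIA,
                 11, 12, 13, 14, 15, 16, 17, 18):
        if not (labels == code).any():
            raise ValueError(f"grid too small: label {code} is empty")
    return vol


def phantom_radii_mm(shape, voxel_size=(1.0, 1.0, 1.0)) -> dict:
    """Nominal ventricle / WM / cortex radii of the phantom, in mm."""
    half_extent = min(s * v for s, v in zip(shape, voxel_size)) / 2.0
    return {"ventricle": _R_VENT * half_extent,
            "wm_outer": _R_WM * half_extent,
            "cortex_outer": _R_WM * half_extent + _CORTEX_VOXELS * max(voxel_size)}


class LesionPlanter:
    """Reusable lesion sampler for one phantom geometry + weight vector.

    Precomputes the per-voxel sampling CDF so that planting for a whole
    cohort costs only the draws themselves.
    """

    def __init__(self, labels: LabelVolume, parc: ParcellationVolume,
                 params: GeneratorParams):
        self.labels = labels
        self.parc = parc
        self.params = params
        self.tiv_voxels = int(np.count_nonzero(labels.data))
        w = params.spatial_weight_vector()
        flat = parc.data.ravel()
        self._voxel_idx = np.flatnonzero(flat)
        codes = flat[self._voxel_idx]
        counts = np.bincount(codes, minlength=37).astype(float)
        nonempty = counts[1:] > 0
        w = np.where(nonempty, w, 0.0)
        if w.sum() <= 0:
            raise ValueError("all weighted regions are empty in this phantom")
        w = w / w.sum()
        p = w[codes - 1] / counts[codes]
        self._cdf = np.cumsum(p / p.sum())

    def plant(self, lesion_fraction: float,
              rng: np.random.Generator) -> LesionProbabilityVolume:
        """Probability volume whose total mass is ``lesion_fraction`` x TIV."""
        if lesion_fraction < 0:
            raise ValueError("lesion fraction must be non-negative")
        delta = self.params.lesion_increment
        mass_voxels = lesion_fraction * self.tiv_voxels
        m = int(round(mass_voxels / delta))
        prob = np.zeros(self.parc.data.size, dtype=np.float32)
        if m > 0:
            u = rng.random(m)
            pos = np.minimum(np.searchsorted(self._cdf, u),
                             len(self._voxel_idx) - 1)
            hits = self._voxel_idx[pos]
            np.add.at(prob, hits, delta)
            np.clip(prob, 0.0, 1.0, out=prob)
        return LesionProbabilityVolume(prob.reshape(self.parc.shape),
                                       self.parc.voxel_size)


def generate_brain(participant: pd.Series | dict, params: GeneratorParams,
                   shape: tuple[int, int, int] | None = None,
                   rng: np.random.Generator | None = None,
                   planter: LesionPlanter | None = None,
                   ) -> tuple[LabelVolume, LesionProbabilityVolume]:
    """Synthetic (label, lesion-probability) volume pair for one participant.

    The planted lesion volume preserves the participant's WMH fraction of
    TIV (``wmh_total_cm3 / tiv_cm3``), drawn upstream from the cohort
    copula conditioned on age and hypertension through the rank links.
    Deterministic given (params.seed, participant id) unless ``rng`` given.
    """
    if planter is None:
        labels = build_label_volume(shape or params.grid_shape, params.voxel_size)
        planter = LesionPlanter(labels, build_parcellation(labels), params)
    if rng is None:
        import zlib
        pid = str(participant["id"]) if "id" in participant else "anon"
        rng = np.random.default_rng(
            (params.seed * 1000003 + zlib.crc32(pid.encode())) % (2 ** 31))
    frac = float(participant["wmh_total_cm3"]) / float(participant["tiv_cm3"])
    return planter.labels, planter.plant(frac, rng)
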