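"""Bullseye parcellation of the cerebral white matter.

Every supratentorial WM (or basal-ganglia) voxel receives a normalized
depth ``f = d_v / (d_v + d_c)`` where ``d_v`` and ``d_c`` are Euclidean
distances in mm to the ventricular surface and the cortical sheet.  Depth
is binned into four equidistant layers (1 = periventricular, 4 =
juxtacortical) and crossed with nine lobar segments (four lobes x two
hemispheres plus the basal ganglia), yielding 36 regions.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import SEGMENTS
from .volumes import (LABEL_BASAL_GANGLIA, LABEL_CORTEX, LABEL_VENTRICLES,
                      LOBAR_LABELS, DepthVolume, LabelVolume,
                      ParcellationVolume)

#: anatomical label -> segment abbreviation
LABEL_TO_SEGMENT = dict(LOBAR_LABELS)
LABEL_TO_SEGMENT[LABEL_BASAL_GANGLIA] = "BG"

_SEG_INDEX = {seg: i for i, seg in enumerate(SEGMENTS)}


def region_code(segment: str, layer: int) -> int:
    """Bijection (segment, layer) <-> code 1..36."""
    if segment not in _SEG_INDEX:
        raise ValueError(f"unknown segment {segment!r}")
    if layer not in (1, 2, 3, 4):
        raise ValueError("layer must be 1..4")
    return 4 * _SEG_INDEX[segment] + layer


def region_spec(code: int) -> tuple[str, int]:
    """Inverse of :func:`region_code`."""
    if not 1 <= code <= 36:
        raise ValueError("region code must lie in 1..36")
    return SEGMENTS[(code - 1) // 4], (code - 1) % 4 + 1


def region_table(parc: ParcellationVolume | None = None) -> pd.DataFrame:
    """The 36-row region table (code, segment, layer[, voxels, volume_cm3])."""
    rows = [{"code": c, "segment": region_spec(c)[0], "layer": region_spec(c)[1]}
            for c in range(1, 37)]
    df = pd.DataFrame(rows)
    if parc is not None:
        counts = np.bincount(parc.data.ravel(), minlength=37)
        df["voxels"] = counts[1:37]
        df["volume_cm3"] = df["voxels"] * parc.voxel_volume_mm3 / 1000.0
    return df


def compute_depth(labels: LabelVolume) -> DepthVolume:
    """Normalized ventricle-to-cortex depth on the WM+BG mask, NaN elsewhere."""
    vent = labels.data == LABEL_VENTRICLES
    cortex = labels.data == LABEL_CORTEX
    if not vent.any():
        raise ValueError("ventricular mask is empty")
    if not cortex.any():
        raise ValueError("cortical mask is empty")
    if (vent & cortex).any():
        raise ValueError("ventricular and cortical masks overlap")
    d_v = ndimage.distance_transform_edt(~vent, sampling=labels.voxel_size)
    d_c = ndimage.distance_transform_edt(~cortex, sampling=labels.voxel_size)
    mask = labels.wm_mask
    f = np.full(labels.shape, np.nan)
    denom = d_v[mask] + d_c[mask]
    f[mask] = d_v[mask] / denom
    return DepthVolume(f, labels.voxel_size)


def assign_layers(depth: DepthVolume) -> np.ndarray:
    """Bin depth into 4 equidistant layers: [0,.25) [.25,.5) [.5,.75) [.75,1].

    Half-open bins with the top bin closed, so voxels touching the cortex
    (f = 1) are juxtacortical.  Returns an int grid, 0 where depth is NaN.
    """
    f = depth.data
    mask = ~np.isnan(f)
    layers = np.zeros(f.shape, dtype=np.int16)
    layers[mask] = np.minimum((f[mask] / 0.25).astype(np.int16) + 1, 4)
    return layers


def build_parcellation(labels: LabelVolume) -> ParcellationVolume:
    """Cross the 9 lobar/BG segments with the 4 depth layers -> codes 1..36."""
    mask = labels.wm_mask
    lab = labels.data[mask]
    known = np.isin(lab, list(LABEL_TO_SEGMENT))
    if not known.all():
        bad = sorted(set(lab[~known].tolist()))
        raise ValueError(f"WM voxels carry non-lobar labels: {bad}")
    layers = assign_layers(compute_depth(labels))

    seg_idx_of_label = np.full(max(LABEL_TO_SEGMENT) + 1, -1, dtype=np.int16)
    for label, seg in LABEL_TO_SEGMENT.items():
        seg_idx_of_label[label] = _SEG_INDEX[seg]
    codes = np.zeros(labels.shape, dtype=np.int16)
    codes[mask] = 4 * seg_idx_of_label[labels.data[mask]] + layers[mask]
    return ParcellationVolume(codes, labels.voxel_size)
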