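"""Lesion volumetry: probability-weighted WMH volumes, global and per region.

Volumes are *soft*: a region's lesion volume is the voxel volume times the
sum of the lesion-probability map over that region - no threshold is ever
applied.  Outputs are reported in cm^3 and as a percentage of the total
intracranial volume (TIV = all non-background voxels, including ventricles
and CSF).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import GeneratorParams
from .parcellation import build_parcellation, region_spec
from .phantom import LesionPlanter, build_label_volume
from .volumes import (LabelVolume, LesionProbabilityVolume,
                      ParcellationVolume, check_aligned)

logger = logging.getLogger(__name__)

REGION_COLUMNS = [f"{region_spec(c)[0]}_L{region_spec(c)[1]}"
                  for c in range(1, 37)]


def compute_tiv(labels: LabelVolume) -> float:
    """Total intracranial volume in cm^3: all non-background voxels."""
    n = int(np.count_nonzero(labels.data))
    if n == 0:
        raise ValueError("label volume has no non-background voxels")
    return n * labels.voxel_volume_mm3 / 1000.0


def regional_load(prob: LesionProbabilityVolume, parc: ParcellationVolume,
                  tiv: float) -> pd.Series:
    """One participant's outcome row: global + 36 regional WMH volumes.

    Returns a Series with ``tiv_cm3``, ``wmh_global_cm3``,
    ``wmh_global_pct_tiv`` and, for every region, ``<SEG>_L<k>_cm3`` and
    ``<SEG>_L<k>_pct_tiv``.
    """
    check_aligned(prob, parc)
    if tiv <= 0:
        raise ValueError("TIV must be positive")
    p = prob.data.ravel().astype(float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("lesion probabilities must lie in [0, 1]")
    codes = parc.data.ravel()
    sums = np.bincount(codes, weights=p, minlength=37)
    if sums[0] > 0:
        logger.warning("lesion probability mass (%.3g voxel units) outside the "
                       "parcellation mask contributes nothing", sums[0])
    voxvol = prob.voxel_volume_mm3 / 1000.0  # cm^3
    regional = sums[1:37] * voxvol
    global_cm3 = regional.sum()
    out = {"tiv_cm3": tiv,
           "wmh_global_cm3": global_cm3,
           "wmh_global_pct_tiv": 100.0 * global_cm3 / tiv}
    for name, vol in zip(REGION_COLUMNS, regional):
        out[f"{name}_cm3"] = vol
        out[f"{name}_pct_tiv"] = 100.0 * vol / tiv
    return pd.Series(out)


def quantify_cohort(cohort: pd.DataFrame, params: GeneratorParams,
                    shape: tuple[int, int, int] | None = None,
                    labels: LabelVolume | None = None,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate each participant's lesion volume and quantify it.

    The phantom geometry (and hence its parcellation) is shared across the
    cohort; only the planted lesions differ.  Per-participant streams derive
    from ``params.seed`` and the participant id unless ``rng`` is given.
    """
    import zlib

    if labels is None:
        labels = build_label_volume(shape or params.grid_shape, params.voxel_size)
    parc = build_parcellation(labels)
    planter = LesionPlanter(labels, parc, params)
    tiv = compute_tiv(labels)

    rows = []
    for _, part in cohort.iterrows():
        if rng is None:
            prng = np.random.default_rng(
                (params.seed * 1000003 + zlib.crc32(str(part["id"]).encode()))
                % (2 ** 31))
        else:
            prng = rng
        frac = float(part["wmh_total_cm3"]) / float(part["tiv_cm3"])
        prob = planter.plant(frac, prng)
        row = regional_load(prob, parc, tiv)
        row["id"] = part["id"]
        rows.append(row)
    out = pd.DataFrame(rows).set_index("id").reset_index()
    return out


def outcome_matrix(wmh_table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant %TIV outcomes keyed 'global' and region codes 1..36."""
    cols = {"global": wmh_table["wmh_global_pct_tiv"]}
    for code in range(1, 37):
        seg, layer = region_spec(code)
        cols[code] = wmh_table[f"{seg}_L{layer}_pct_tiv"]
    return pd.DataFrame(cols, index=wmh_table.index)
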