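"""Bullseye construction: depth field, layer binning, 36-region partition."""
import numpy as np
import pytest

from wmh_bullseye import (DepthVolume, LabelVolume, assign_layers,
                          build_label_volume, build_parcellation,
                          compute_depth, region_code, region_spec,
                          region_table)
from wmh_bullseye.config import SEGMENTS
from wmh_bullseye.phantom import phantom_radii_mm


def slab_labels(n=11):
    """Flat phantom: ventricle plane at x=0, cortex plane at x=n-1, WM between."""
    lab = np.zeros((n, 5, 5), dtype=np.int16)
    lab[0] = 2
    lab[n - 1] = 1
    lab[1:n - 1] = 11
    return LabelVolume(lab)


def test_region_code_bijection():
    codes = {region_code(seg, layer) for seg in SEGMENTS for layer in (1, 2, 3, 4)}
    assert codes == set(range(1, 37))
    for c in range(1, 37):
        assert region_code(*region_spec(c)) == c


def test_depth_midpoint_is_half():
    f = compute_depth(slab_labels(11)).data
    assert f[5, 2, 2] == pytest.approx(0.5)
    # adjacent to the ventricular plane: strongly periventricular
    assert f[1, 2, 2] < 0.25
    assert f[9, 2, 2] > 0.75


def test_depth_respects_anisotropic_voxels():
    lab = slab_labels(11)
    lab3 = LabelVolume(lab.data, voxel_size=(3.0, 1.0, 1.0))
    # normalized depth is scale-free along the slab axis
    f1 = compute_depth(lab)
    f3 = compute_depth(lab3)
    np.testing.assert_allclose(f1.data[5, 2, 2], f3.data[5, 2, 2])


def test_depth_requires_both_surfaces():
    lab = slab_labels(11)
    no_vent = lab.data.copy()
    no_vent[no_vent == 2] = 0
    with pytest.raises(ValueError, match="ventricular"):
        compute_depth(LabelVolume(no_vent))
    no_cortex = lab.data.copy()
    no_cortex[no_cortex == 1] = 0
    with pytest.raises(ValueError, match="cortical"):
        compute_depth(LabelVolume(no_cortex))


def test_spherical_phantom_depth_matches_analytic_profile(phantom_labels):
    radii = phantom_radii_mm(phantom_labels.shape)
    r_v, r_c = radii["ventricle"], radii["wm_outer"]
    idx = np.indices(phantom_labels.shape, dtype=float)
    centre = (np.array(phantom_labels.shape) - 1) / 2
    r = np.sqrt(((idx - centre[:, None, None, None]) ** 2).sum(axis=0))
    f = compute_depth(phantom_labels).data
    mask = phantom_labels.wm_mask
    expected = np.clip((r[mask] - r_v) / (r_c - r_v), 0, 1)
    assert np.abs(f[mask] - expected).max() <= 1.5 / (r_c - r_v)


def test_layer_bins_are_half_open_with_closed_top():
    f = np.full((1, 1, 6), np.nan)
    f[0, 0, :5] = [0.0, 0.25, 0.5, 0.75, 1.0]
    layers = assign_layers(DepthVolume(f))
    assert layers[0, 0, :5].tolist() == [1, 2, 3, 4, 4]
    assert layers[0, 0, 5] == 0  # undefined depth -> no layer


def test_default_phantom_yields_36_nonempty_regions(phantom_parcellation):
    counts = np.bincount(phantom_parcellation.data.ravel(), minlength=37)
    assert (counts[1:37] > 0).all()


def test_parcellation_partitions_wm_mask(phantom_labels, phantom_parcellation):
    mask = phantom_labels.wm_mask
    codes = phantom_parcellation.data
    assert ((codes > 0) == mask).all()
    counts = np.bincount(codes.ravel(), minlength=37)
    assert counts[1:37].sum() == mask.sum()


def test_single_wedge_phantom_has_exactly_four_codes(phantom_labels):
    lab = phantom_labels.data.copy()
    lab[(lab == 3) | (lab >= 11)] = 11  # everything WM becomes left frontal
    parc = build_parcellation(LabelVolume(lab))
    codes = set(np.unique(parc.data)) - {0}
    assert codes == {region_code("FL", layer) for layer in (1, 2, 3, 4)}


def test_brute_force_voxel_oracle(phantom_labels, phantom_parcellation, rng):
    """Recompute (segment, layer) per voxel from first principles."""
    lab = phantom_labels.data
    vent = np.argwhere(lab == 2).astype(float)
    cortex = np.argwhere(lab == 1).astype(float)
    wm_vox = np.argwhere(phantom_labels.wm_mask)
    pick = wm_vox[rng.choice(len(wm_vox), 1000, replace=False)]
    seg_of_label = {3: "BG", 11: "FL", 12: "FR", 13: "PL", 14: "PR",
                    15: "TL", 16: "TR", 17: "OL", 18: "OR"}
    for v in pick:
        d_v = np.sqrt(((vent - v) ** 2).sum(axis=1)).min()
        d_c = np.sqrt(((cortex - v) ** 2).sum(axis=1)).min()
        f = d_v / (d_v + d_c)
        layer = min(int(f / 0.25) + 1, 4)
        code = region_code(seg_of_label[lab[tuple(v)]], layer)
        assert phantom_parcellation.data[tuple(v)] == code


def test_layers_monotone_along_radial_rays(phantom_labels, rng):
    layers = assign_layers(compute_depth(phantom_labels))
    centre = (np.array(phantom_labels.shape) - 1) / 2
    radii = phantom_radii_mm(phantom_labels.shape)
    for _ in range(50):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        seq = []
        for r in np.linspace(radii["ventricle"] + 1, radii["wm_outer"] - 1, 40):
            v = tuple(np.round(centre + r * d).astype(int))
            if phantom_labels.wm_mask[v]:
                seq.append(layers[v])
        assert all(b >= a for a, b in zip(seq, seq[1:]))


def test_layers_are_equidistant_in_radius(phantom_labels):
    """Each layer spans ~one quarter of the shell thickness (within a voxel)."""
    layers = assign_layers(compute_depth(phantom_labels))
    idx = np.indices(phantom_labels.shape, dtype=float)
    centre = (np.array(phantom_labels.shape) - 1) / 2
    r = np.sqrt(((idx - centre[:, None, None, None]) ** 2).sum(axis=0))
    radii = phantom_radii_mm(phantom_labels.shape)
    quarter = (radii["wm_outer"] - radii["ventricle"]) / 4
    for layer in (1, 2, 3, 4):
        sel = layers == layer
        thickness = r[sel].max() - r[sel].min()
        assert abs(thickness - quarter) <= 1.5


def test_parcellation_is_deterministic(phantom_labels):
    a = build_parcellation(phantom_labels)
    b = build_parcellation(phantom_labels)
    np.testing.assert_array_equal(a.data, b.data)


def test_region_table_contents(phantom_parcellation):
    tbl = region_table(phantom_parcellation)
    assert len(tbl) == 36
    assert tbl["voxels"].sum() == (phantom_parcellation.data > 0).sum()
    np.testing.assert_allclose(tbl["volume_cm3"], tbl["voxels"] / 1000.0)


def test_grid_too_small_raises():
    with pytest.raises(ValueError, match="too small"):
        build_label_volume((16, 16, 16))


def test_nifti_roundtrip(tmp_path, phantom_labels):
    path = tmp_path / "labels.nii.gz"
    phantom_labels.save(path)
    back = LabelVolume.load(path)
    np.testing.assert_array_equal(back.data, phantom_labels.data)
    assert back.voxel_size == phantom_labels.voxel_size
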