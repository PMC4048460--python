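"""Markers from labeled volumes: surfaces, centroids, volumes, tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proximark import regionstats as rs
from proximark.regionstats import (
    GroupingDef,
    FractionDefs,
    centroid_divergence,
    centroid_voxel_mean,
    connectivity_matrix,
    contact_face_counts,
    delta_table,
    load_groupings,
    marker_table,
    region_volumes,
    surface_faces,
    volume_fractions,
)

from conftest import brute_force_contacts, make_volume, random_connected_solid


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------


def test_surface_faces_worked_examples():
    # isolated voxel: a cube, 6 faces all to background
    labels = np.zeros((5, 5, 5), dtype=int)
    labels[2, 2, 2] = 1
    sf = surface_faces(make_volume(labels), 1)
    assert sf.total_faces == 6 and sf.contact_faces == {0: 6}

    # 2x1x1 bar: 12 faces minus the 2 internal ones
    labels = np.zeros((5, 5, 5), dtype=int)
    labels[1:3, 2, 2] = 1
    assert surface_faces(make_volume(labels), 1).total_faces == 10

    # voxel in the grid corner: out-of-grid neighbors still count as background
    labels = np.zeros((3, 3, 3), dtype=int)
    labels[0, 0, 0] = 1
    sf = surface_faces(make_volume(labels), 1)
    assert sf.total_faces == 6 and sf.contact_faces == {0: 6}


def test_connectivity_nonsymmetry_worked_example():
    """Single voxel touching a 2x1x1 bar: 100/6 vs 100/10 percent."""
    labels = np.zeros((6, 6, 6), dtype=int)
    labels[2, 2, 2] = 1          # region A, single voxel
    labels[3, 2, 2] = 2          # region B, 2x1x1 bar
    labels[4, 2, 2] = 2
    vol = make_volume(labels, names={1: "A", 2: "B"})
    cm = connectivity_matrix(vol, GroupingDef("pair", ("A", "B")))
    assert cm.values[0, 1] == pytest.approx(100.0 / 6.0, abs=1e-12)
    assert cm.values[1, 0] == pytest.approx(10.0, abs=1e-12)
    assert cm.values[0, 0] == 0.0 and cm.values[1, 1] == 0.0


def test_connectivity_no_shared_faces_is_zero_both_ways():
    labels = np.zeros((8, 8, 8), dtype=int)
    labels[1, 1, 1] = 1
    labels[6, 6, 6] = 2
    cm = connectivity_matrix(
        make_volume(labels, names={1: "A", 2: "B"}), GroupingDef("pair", ("A", "B"))
    )
    assert cm.values[0, 1] == 0.0 and cm.values[1, 0] == 0.0


def test_contact_counts_match_brute_force_on_random_volumes(rng):
    """Vectorized face census equals triple-loop enumeration, integer-exact."""
    for _ in range(10):
        labels = rng.integers(0, 4, size=(6, 6, 6))
        fast = contact_face_counts(labels)
        slow = brute_force_contacts(labels)
        np.testing.assert_array_equal(fast[1:, :], slow[1:, :])


def test_row_sum_closure(rng):
    """Contact percentages over all labels plus background sum to 100."""
    labels = rng.integers(0, 5, size=(7, 7, 7))
    labels[1, 1, 1] = 1  # ensure region 1 exists
    vol = make_volume(labels)
    sf = surface_faces(vol, 1)
    total_pct = 100.0 * sum(sf.contact_faces.values()) / sf.total_faces
    assert total_pct == pytest.approx(100.0, abs=1e-9)


def test_connectivity_denominator_uses_full_volume_surface():
    """Restricting the grouping must not change a region's surface."""
    labels = np.zeros((6, 6, 6), dtype=int)
    labels[2, 2, 2] = 1
    labels[3, 2, 2] = 2
    labels[1, 2, 2] = 3  # extra neighbor not in the grouping
    vol = make_volume(labels, names={1: "A", 2: "B", 3: "C"})
    cm = connectivity_matrix(vol, GroupingDef("pair", ("A", "B")))
    assert cm.values[0, 1] == pytest.approx(100.0 / 6.0)  # not 100/5


def test_connectivity_empty_region_row_is_zero(caplog):
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[1, 1, 1] = 1
    vol = make_volume(np.asarray(labels), names={1: "A", 2: "gone"})
    cm = connectivity_matrix(vol, GroupingDef("g", ("A", "gone")))
    assert (cm.values[1] == 0).all() and (cm.values[:, 1] == 0).all()


def test_connectivity_translation_invariance(rng):
    base = np.zeros((10, 10, 10), dtype=int)
    base[2:4, 2:4, 2:4] = 1
    base[4, 2, 2] = 2
    g = GroupingDef("g", ("region-1", "region-2"))
    cm1 = connectivity_matrix(make_volume(base), g)
    cm2 = connectivity_matrix(make_volume(np.roll(base, (3, 2, 1), axis=(0, 1, 2))), g)
    np.testing.assert_allclose(cm1.values, cm2.values)


# ---------------------------------------------------------------------------
# volumes and centroids
# ---------------------------------------------------------------------------


def test_region_volume_definition_and_anisotropic_spacing():
    labels = np.zeros((5, 5, 5), dtype=int)
    labels.ravel()[:10] = 0
    labels[0, 0, :5] = 1
    labels[1, 0, :5] = 1  # 10 voxels
    assert region_volumes(make_volume(labels))["region-1"] == pytest.approx(10.0)
    # typical acquisition spacing 1.25 x 1.25 x 1.2 mm
    vol = make_volume(labels, spacing=(1.25, 1.25, 1.2))
    assert region_volumes(vol)["region-1"] == pytest.approx(18.75)
    # named but absent region has zero volume
    vol2 = make_volume(labels, names={1: "present", 9: "absent"})
    assert region_volumes(vol2)["absent"] == 0.0


def test_centroid_voxel_mean_examples():
    labels = np.zeros((6, 6, 6), dtype=int)
    labels[2, 3, 4] = 1
    np.testing.assert_allclose(centroid_voxel_mean(make_volume(labels), 1), [2.5, 3.5, 4.5])
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[0:2, 0:2, 0:2] = 2
    np.testing.assert_allclose(centroid_voxel_mean(make_volume(labels), 2), [1.0, 1.0, 1.0])


def test_centroid_translation_equivariance():
    labels = np.zeros((8, 8, 8), dtype=int)
    labels[1:3, 2:5, 3] = 1
    spacing = (0.7, 1.1, 1.3)
    c1 = centroid_voxel_mean(make_volume(labels, spacing=spacing), 1)
    c2 = centroid_voxel_mean(make_volume(np.roll(labels, 1, axis=0), spacing=spacing), 1)
    np.testing.assert_allclose(c2 - c1, [spacing[0], 0, 0], atol=1e-12)


def test_centroid_rotation_permutes_coordinates():
    labels = np.zeros((7, 7, 7), dtype=int)
    labels[1:3, 2:6, 3:5] = 1
    c = centroid_voxel_mean(make_volume(labels), 1)
    rot = np.rot90(labels, k=1, axes=(0, 1))
    cr = centroid_voxel_mean(make_volume(np.ascontiguousarray(rot)), 1)
    # rot90 maps voxel (x, y, z) to (N - y, x, z), so coordinates permute
    n = labels.shape[1]
    np.testing.assert_allclose(cr, [n - c[1], c[0], c[2]], atol=1e-12)


def test_centroid_divergence_single_voxel_closed_form():
    """Unit voxel spanning [2,3]x[3,4]x[4,5]: per-axis (3^2-2^2)/2 / V."""
    labels = np.zeros((6, 6, 6), dtype=int)
    labels[2, 3, 4] = 1
    np.testing.assert_allclose(centroid_divergence(make_volume(labels), 1), [2.5, 3.5, 4.5],
                               atol=1e-12)


def test_centroid_divergence_l_shape_hand_computed():
    labels = np.zeros((5, 5, 5), dtype=int)
    labels[1, 1, 1] = 1
    labels[2, 1, 1] = 1
    labels[2, 2, 1] = 1
    expected = np.array([(1.5 + 2.5 + 2.5) / 3, (1.5 + 1.5 + 2.5) / 3, 1.5])
    np.testing.assert_allclose(centroid_divergence(make_volume(labels), 1), expected, atol=1e-12)


def test_centroid_methods_agree_on_random_solids(rng):
    """Surface-integral centroid equals the voxel mean on arbitrary solids."""
    for i in range(8):
        mask = random_connected_solid(rng, n_voxels=int(rng.integers(5, 60)))
        labels = mask.astype(int)
        vol = make_volume(labels, spacing=(0.9, 1.1, 1.3))
        a = centroid_voxel_mean(vol, 1)
        b = centroid_divergence(vol, 1)
        np.testing.assert_allclose(b, a, rtol=1e-9)


def test_empty_region_centroid_raises():
    labels = np.zeros((3, 3, 3), dtype=int)
    labels[0, 0, 0] = 1
    vol = make_volume(labels, names={1: "A", 2: "B"})
    with pytest.raises(ValueError):
        centroid_voxel_mean(vol, "B")
    with pytest.raises(ValueError):
        centroid_divergence(vol, "B")


# ---------------------------------------------------------------------------
# volume fractions
# ---------------------------------------------------------------------------


def _fraction_volume():
    labels = np.zeros((10, 10, 10), dtype=int)
    labels[0:4, :, :] = 1      # CSF-like: 400
    labels[4:9, :, :] = 2      # brain tissue: 500
    labels[9, :, 0:3] = 3      # hippocampus: 30
    names = {1: "CSF", 2: "tissue", 3: "hippo"}
    return make_volume(labels, names=names)


def test_volume_fractions_integer_ratio_oracle():
    vol = _fraction_volume()
    defs = FractionDefs(icv_regions=("CSF", "tissue", "hippo"),
                        excluded_from_wb=("CSF",), hippocampus_regions=("hippo",))
    vf = volume_fractions(vol, defs)
    assert vf.wb_fraction == pytest.approx(530 / 930)
    assert vf.hp_fraction == pytest.approx(30 / 930)
    assert vf.hp_fraction < vf.wb_fraction


def test_volume_fractions_scale_invariance_and_degenerate_csf():
    vol = _fraction_volume()
    defs = FractionDefs(icv_regions=("CSF", "tissue", "hippo"),
                        excluded_from_wb=("CSF",), hippocampus_regions=("hippo",))
    vf1 = volume_fractions(vol, defs)
    doubled = make_volume(vol.labels, spacing=(2, 2, 2), names=dict(vol.label_names))
    vf2 = volume_fractions(doubled, defs)
    assert vf1.wb_fraction == pytest.approx(vf2.wb_fraction)
    # no CSF at all: whole brain is the whole intracranial volume
    defs_nocsf = FractionDefs(icv_regions=("tissue", "hippo"),
                              excluded_from_wb=(), hippocampus_regions=("hippo",))
    assert volume_fractions(vol, defs_nocsf).wb_fraction == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# groupings
# ---------------------------------------------------------------------------


def test_shipped_study_groupings_counts_and_feature_dimensions():
    g = load_groupings("paper")
    assert len(g["all"]) == 37
    assert len(g["func"]) == 26
    assert len(g["potato"]) == 16
    # surface feature dimensionality K(K-1)
    assert len(g["func"]) * (len(g["func"]) - 1) == 650
    assert len(g["potato"]) * (len(g["potato"]) - 1) == 240
    # func and potato both draw from the full region set
    assert set(g["func"].region_names) <= set(g["all"].region_names)
    assert set(g["potato"].region_names) <= set(g["all"].region_names)


def test_phantom_groupings_resolve_against_phantom_atlas():
    from proximark.phantom import build_atlas, default_phantom_spec

    vol = build_atlas(default_phantom_spec((24, 24, 24)))
    for gdef in load_groupings("phantom").values():
        cm = connectivity_matrix(vol, gdef)
        assert cm.values.shape == (len(gdef), len(gdef))
        assert np.all(np.diag(cm.values) == 0)
        assert cm.values.min() >= 0 and cm.values.max() <= 100


# ---------------------------------------------------------------------------
# marker tables
# ---------------------------------------------------------------------------


def _grid_of_cubes(region_names):
    """Pack one 2^3 cube per region into a labeled volume (for table tests)."""
    k = len(region_names)
    side = int(np.ceil(k ** (1 / 3)))
    labels = np.zeros((side * 3, side * 3, side * 3), dtype=int)
    names = {}
    for i, name in enumerate(region_names):
        x, y, z = np.unravel_index(i, (side,) * 3)
        labels[3 * x: 3 * x + 2, 3 * y: 3 * y + 2, 3 * z: 3 * z + 2] = i + 1
        names[i + 1] = name
    return make_volume(labels, names=names)


def _toy_manifest(n=3, timepoints=("bl",)):
    rows = []
    for i in range(n):
        for tp in timepoints:
            rows.append({"id": f"s{i}", "diagnosis": "NC", "converter": False,
                         "age_bl": 70 + i, "sex": "F", "timepoint": tp, "path": ""})
    return pd.DataFrame(rows)


def test_marker_table_feature_counts_for_study_groupings():
    g = load_groupings("paper")
    for name, expected in [("func", 650), ("potato", 240)]:
        vol = _grid_of_cubes(g[name].region_names)
        table = marker_table(_toy_manifest(), "surface", g[name],
                            loader=lambda row, v=vol: v)
        assert len(rs.feature_columns(table)) == expected


def test_marker_table_landmarks_and_fraction_shapes():
    g = load_groupings("paper")["potato"]
    vol = _grid_of_cubes(g.region_names)
    lm = marker_table(_toy_manifest(), "landmarks", g, loader=lambda row: vol)
    assert len(rs.feature_columns(lm)) == 3 * 16
    defs = FractionDefs(icv_regions=g.region_names,
                        excluded_from_wb=("Left-Lateral-Ventricle", "Right-Lateral-Ventricle"),
                        hippocampus_regions=("Left-Hippocampus", "Right-Hippocampus"))
    hp = marker_table(_toy_manifest(), "hp_fraction", fraction_defs=defs, loader=lambda row: vol)
    assert rs.feature_columns(hp) == ["hp_fraction"]
    assert list(hp.columns[:6]) == rs.META_COLUMNS


def test_delta_table_identity_sign_and_exclusion():
    g = load_groupings("paper")["potato"]
    vol = _grid_of_cubes(g.region_names)
    bl = marker_table(_toy_manifest(timepoints=("bl",)), "surface", g, loader=lambda row: vol)
    m12 = bl.copy()
    m12.attrs["kind"] = "surface"
    m12["timepoint"] = "m12"
    d = delta_table(bl, m12, "surface")
    assert (d[rs.feature_columns(d)].to_numpy() == 0).all()
    assert (d["timepoint"] == "delta").all()

    # volume markers flip the sign: positive delta = volume loss
    blv = pd.DataFrame({"id": ["a", "b"], "diagnosis": ["NC", "AD"], "converter": [False, False],
                        "age_bl": [70, 80], "sex": ["F", "M"], "timepoint": ["bl", "bl"],
                        "hp_fraction": [0.0045, 0.0035]})
    m12v = blv.copy()
    m12v["hp_fraction"] = [0.0044, 0.0033]
    dv = delta_table(blv, m12v, "hp_fraction")
    np.testing.assert_allclose(dv["hp_fraction"], [0.0001, 0.0002])

    # subject missing at one timepoint is dropped with a warning
    with pytest.warns(UserWarning, match="one timepoint only"):
        d2 = delta_table(blv, m12v.iloc[:1], "hp_fraction")
    assert list(d2["id"]) == ["a"]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_connectivity_percentages_bounded_and_diagonal_zero(seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 4, size=(6, 6, 6))
    present = [int(l) for l in np.unique(labels) if l != 0]
    if len(present) < 2:
        return
    vol = make_volume(labels)
    g = GroupingDef("g", tuple(f"region-{l}" for l in present))
    cm = connectivity_matrix(vol, g)
    assert np.all(np.diag(cm.values) == 0)
    assert cm.values.min() >= 0.0 and cm.values.max() <= 100.0
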