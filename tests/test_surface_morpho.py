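import numpy as np
import pytest

from memcurve import surface_morpho as sm
from memcurve import synthetic_scenes as syn
from memcurve.volio import LabelVolume


def blob_volume(sizes, voxel=10.0, label=1, shape=(80, 20, 20), gap=5):
    """Rectangular blobs of exactly the given voxel counts, spaced along x."""
    labels = np.zeros(shape, dtype=np.int8)
    x = 1
    for count in sizes:
        cols = count // 16
        rest = count - cols * 16
        labels[x:x + cols, 2:6, 2:6] = label
        if rest:
            labels[x + cols, 2:2 + rest, 2] = label
        x += cols + gap + 2
    assert (labels == label).sum() == sum(sizes)
    return LabelVolume(labels=labels, voxel_size=voxel,
                       class_table={0: "background", 1: "membrane",
                                    2: "coat"})


class TestRemoveSmallComponents:
    @pytest.mark.parametrize("count,survives", [(149, False), (150, True)])
    def test_island_threshold_is_strict_less_than(self, count, survives):
        vol = blob_volume([count], shape=(60, 20, 20))
        out = sm.remove_small_components(vol, 150)
        assert ((out.labels == 1).sum() > 0) == survives

    def test_large_component_untouched(self):
        vol = blob_volume([500], shape=(80, 20, 20))
        out = sm.remove_small_components(vol, 150)
        assert (out.labels == 1).sum() == 500

    def test_classes_processed_independently(self):
        """A small coat island inside a large membrane: only the island
        goes; component counting never merges classes."""
        labels = np.zeros((40, 40, 40), dtype=np.int8)
        labels[5:25, 5:25, 5:25] = 1          # 8000-voxel membrane block
        labels[10:14, 10:14, 10:14] = 2       # 64-voxel coat island inside
        vol = LabelVolume(labels, 10.0)
        out = sm.remove_small_components(vol, 150)
        assert (out.labels == 2).sum() == 0
        assert (out.labels == 1).sum() == 8000 - 64

    def test_26_connectivity_keeps_diagonal_chains(self):
        labels = np.zeros((200, 8, 8), dtype=np.int8)
        for i in range(160):                   # diagonal chain, 26-connected
            labels[i, 2 + (i % 2), 2 + (i % 2)] = 1
        vol = LabelVolume(labels, 10.0, class_table={0: "background",
                                                     1: "membrane"})
        out = sm.remove_small_components(vol, 150)
        assert (out.labels == 1).sum() == 160


class TestExtractSurface:
    def test_sphere_points_at_radius(self, sphere_solid_100):
        s = sm.extract_surface(sphere_solid_100, "membrane",
                               mode="isosurface")
        center = (np.array(sphere_solid_100.shape) - 1) / 2 * 10.0
        r = np.linalg.norm(s[["x", "y", "z"]].to_numpy() - center, axis=1)
        assert np.all(np.abs(r - 100.0) < 10.0)

    def test_slab_normals_align_with_slab_normal(self):
        vol = syn.slab_label_volume(35.0, 600.0, voxel_size=10.0)
        s = sm.extract_surface(vol, "membrane", mode="midsurface")
        nz = np.abs(s["nz"].to_numpy())
        assert np.degrees(np.arccos(np.clip(nz, 0, 1)).max()) < 5.0

    def test_near_edge_flag_distance(self):
        vol = syn.slab_label_volume(35.0, 600.0, voxel_size=10.0)
        s = sm.extract_surface(vol, "membrane", edge_margin=50.0)
        lo, hi = vol.physical_bounds()
        pos = s[["x", "y", "z"]].to_numpy()
        expected = np.any((pos - lo < 50.0) | (hi - pos < 50.0), axis=1)
        assert np.array_equal(s["near_edge"].to_numpy(), expected)

    def test_empty_class_raises(self):
        labels = np.zeros((12, 12, 12), dtype=np.int8)
        labels[4:8, 4:8, 4:8] = 1
        vol = LabelVolume(labels, 10.0)  # 'coat' in table but has no voxels
        with pytest.raises(sm.EmptyClassError):
            sm.extract_surface(vol, "coat")

    def test_area_weights_positive_and_plausible(self, sphere_shell_250):
        s = sm.extract_surface(sphere_shell_250, "membrane")
        assert (s["area_weight"] > 0).all()
        total = s["area_weight"].sum()
        expected = 4 * np.pi * 250.0 ** 2
        assert total == pytest.approx(expected, rel=0.25)

    def test_normals_unit_length(self, sphere_shell_250):
        s = sm.extract_surface(sphere_shell_250, "membrane")
        norms = np.linalg.norm(s[["nx", "ny", "nz"]].to_numpy(), axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_midsurface_collapses_shell_to_single_radius(self,
                                                         sphere_shell_250):
        s = sm.extract_surface(sphere_shell_250, "membrane")
        center = (np.array(sphere_shell_250.shape) - 1) / 2 * 12.0
        r = np.linalg.norm(s[["x", "y", "z"]].to_numpy() - center, axis=1)
        # a two-sheet extraction would put points at 232.5 and 267.5
        assert abs(np.median(r) - 250.0) < 5.0
        assert r.std() < 8.0


class TestEstimateCurvature:
    @pytest.mark.parametrize("fixture,truth,tol", [
        ("sphere500", 0.020, 0.05),
        ("cylinder", 0.040, 0.05),
        ("plane", 0.0, 0.002),
    ])
    def test_analytic_surface_oracles(self, fixture, truth, tol):
        if fixture == "sphere500":
            vol = syn.sphere_label_volume(500.0, voxel_size=10.0)
        elif fixture == "cylinder":
            vol = syn.cylinder_label_volume(176.8, 600.0, voxel_size=10.0)
        else:
            vol = syn.slab_label_volume(100.0, 800.0, voxel_size=10.0)
        s = sm.estimate_curvature(
            sm.extract_surface(vol, "membrane", mode="isosurface"))
        got = np.median(s.loc[s.reliable & ~s.near_edge, "curvedness"])
        if truth > 0:
            assert got == pytest.approx(truth, rel=tol)
        else:
            assert abs(got) < tol

    def test_rotation_invariance_on_rerasterized_sphere(self):
        """Curvedness of a sphere does not depend on grid orientation
        (a sphere re-rasterized after any rotation is the same sphere);
        check the off-center rasterization instead, which shifts the
        staircase phase the same way a rotation would."""
        meds = []
        for jitter in ((0.0, 0.0, 0.0), (3.3, 7.1, 5.2)):
            n = 45
            idx = np.arange(n) * 10.0 - (n - 1) / 2 * 10.0
            d = np.sqrt((idx[:, None, None] - jitter[0]) ** 2
                        + (idx[None, :, None] - jitter[1]) ** 2
                        + (idx[None, None, :] - jitter[2]) ** 2)
            vol = LabelVolume((d <= 150.0).astype(np.int8), 10.0,
                              class_table={0: "background", 1: "membrane"})
            s = sm.estimate_curvature(
                sm.extract_surface(vol, "membrane", mode="isosurface"))
            meds.append(np.median(s.loc[s.reliable, "curvedness"]))
        assert meds[0] == pytest.approx(meds[1], rel=0.03)

    def test_voxel_size_scaling(self):
        """Scaling voxel_size by s scales recovered curvedness by 1/s."""
        base = syn.sphere_label_volume(200.0, voxel_size=10.0)
        scaled = LabelVolume(base.labels.copy(), 20.0,
                             class_table=dict(base.class_table))
        med = []
        for vol in (base, scaled):
            s = sm.estimate_curvature(
                sm.extract_surface(vol, "membrane", mode="isosurface"))
            med.append(np.median(s.loc[s.reliable & ~s.near_edge,
                                       "curvedness"]))
        assert med[0] == pytest.approx(2 * med[1], rel=0.1)

    def test_relative_error_decreases_with_radius(self):
        errs = []
        for r in (100.0, 200.0, 400.0):
            vol = syn.sphere_label_volume(r, voxel_size=10.0)
            s = sm.estimate_curvature(
                sm.extract_surface(vol, "membrane", mode="isosurface"))
            got = np.median(s.loc[s.reliable & ~s.near_edge, "curvedness"])
            errs.append(abs(got * r / 10.0 - 1.0))
        assert errs[0] > errs[1] > errs[2]

    def test_sparse_points_flagged_unreliable(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "x": rng.uniform(0, 1000, 5), "y": rng.uniform(0, 1000, 5),
            "z": rng.uniform(0, 1000, 5),
            "nx": 0.0, "ny": 0.0, "nz": 1.0,
            "area_weight": 1.0, "near_edge": False, "reliable": True,
            "k1": np.nan, "k2": np.nan, "curvedness": np.nan})
        out = sm.estimate_curvature(df, neighborhood_radius=50.0)
        assert (~out["reliable"]).all()
        assert out["curvedness"].isna().all()
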