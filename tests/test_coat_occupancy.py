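import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from memcurve import coat_occupancy as co
from memcurve.volio import LabelVolume


def surface_frame(pos, curvedness=0.04, near_edge=False):
    pos = np.atleast_2d(pos)
    n = len(pos)
    return pd.DataFrame({
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "nx": 0.0, "ny": 0.0, "nz": 1.0,
        "k1": curvedness, "k2": curvedness,
        "curvedness": np.broadcast_to(curvedness, n).astype(float),
        "area_weight": 1.0,
        "near_edge": np.broadcast_to(near_edge, n),
        "reliable": True,
    })


def coat_volume_single_voxel(index=(5, 5, 5), voxel=10.0, shape=(11, 11, 11)):
    labels = np.zeros(shape, dtype=np.int8)
    labels[index] = 2
    return LabelVolume(labels, voxel,
                       class_table={0: "background", 2: "coat"})


class TestLabelProximal:
    @pytest.mark.parametrize("distance,expected", [(49.0, True),
                                                   (50.0, True),
                                                   (51.0, False)])
    def test_threshold_at_50_angstrom(self, distance, expected):
        coat = coat_volume_single_voxel()
        p = np.array([[50.0 + distance, 50.0, 50.0]])
        assert co.label_proximal(surface_frame(p), coat)[0] == expected

    def test_agrees_with_brute_force_on_random_points(self):
        rng = np.random.default_rng(42)
        labels = (rng.random((12, 12, 12)) < 0.02).astype(np.int8) * 2
        labels[0, 0, 0] = 2
        coat = LabelVolume(labels, 10.0,
                           class_table={0: "background", 2: "coat"})
        pts = rng.uniform(0, 110, size=(10000, 3))
        got = co.label_proximal(surface_frame(pts), coat, 50.0)
        centers = np.argwhere(labels == 2) * 10.0
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        expected = d2.min(axis=1) <= 50.0 ** 2
        assert np.array_equal(got, expected)

    def test_empty_coat_warns_and_returns_false(self):
        labels = np.zeros((6, 6, 6), dtype=np.int8)
        coat = LabelVolume(labels, 10.0,
                           class_table={0: "background", 2: "coat"})
        with pytest.warns(UserWarning, match="no voxels"):
            flags = co.label_proximal(surface_frame([[10, 10, 10]]), coat)
        assert not flags.any()


class TestExcludeEdges:
    def test_margin_zero_is_identity(self):
        s = surface_frame(np.random.default_rng(0).uniform(0, 100, (20, 3)),
                          near_edge=False)
        out = co.exclude_edges(s)
        assert len(out) == 20

    def test_flagged_points_removed(self):
        s = surface_frame(np.zeros((10, 3)))
        s.loc[3:5, "near_edge"] = True
        out = co.exclude_edges(s)
        assert len(out) == 7

    def test_all_excluded_raises(self):
        s = surface_frame(np.zeros((4, 3)), near_edge=True)
        with pytest.raises(ValueError, match="margin"):
            co.exclude_edges(s)


class TestBinOccupancy:
    def test_ratio_definition(self):
        s = surface_frame(np.zeros((10, 3)), curvedness=0.041)
        prox = np.array([True] * 7 + [False] * 3)
        prof = co.bin_occupancy(s, prox, bin_width=0.004)
        row = prof.loc[prof.n_points > 0].iloc[0]
        assert row.n_points == 10 and row.n_proximal == 7
        assert row.occupancy == pytest.approx(0.7)

    def test_all_proximal_gives_unit_occupancy(self):
        rng = np.random.default_rng(1)
        s = surface_frame(rng.uniform(0, 100, (50, 3)),
                          curvedness=rng.uniform(0.01, 0.09, 50))
        prof = co.bin_occupancy(s, np.ones(50, dtype=bool))
        assert np.allclose(prof.loc[prof.n_points > 0, "occupancy"], 1.0)

    def test_empty_bins_reported_unset(self):
        s = surface_frame(np.zeros((5, 3)), curvedness=0.05)
        prof = co.bin_occupancy(s, np.zeros(5, dtype=bool), c_max=0.08)
        empty = prof.loc[prof.n_points == 0]
        assert len(empty) > 0 and empty["occupancy"].isna().all()

    def test_bins_contiguous_fixed_width_and_counts_conserved(self):
        rng = np.random.default_rng(2)
        s = surface_frame(rng.uniform(0, 100, (200, 3)),
                          curvedness=rng.uniform(0.0, 0.1, 200))
        prof = co.bin_occupancy(s, rng.random(200) < 0.5, bin_width=0.004)
        assert np.allclose(np.diff(prof.curvedness_lo), 0.004)
        assert np.allclose(prof.curvedness_hi - prof.curvedness_lo, 0.004)
        assert prof.n_points.sum() == 200

    def test_nonpositive_bin_width_rejected(self):
        s = surface_frame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            co.bin_occupancy(s, np.zeros(3, dtype=bool), bin_width=0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6), frac=st.floats(0.0, 1.0))
    def test_occupancy_always_in_unit_interval(self, seed, frac):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 300)
        s = surface_frame(rng.uniform(0, 100, (n, 3)),
                          curvedness=rng.uniform(0, 0.2, n))
        prof = co.bin_occupancy(s, rng.random(n) < frac)
        occ = prof["occupancy"].dropna()
        assert ((occ >= 0) & (occ <= 1)).all()


def ramp_profile(slope=15.0, intercept=0.05, breakpoint=0.06, n_per_bin=500,
                 bin_width=0.004, c_max=0.1, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    lo = np.arange(0.0, c_max, bin_width)
    c = lo + bin_width / 2
    y = np.clip(intercept + slope * np.minimum(c, breakpoint), 0, 1)
    y = np.clip(y + rng.normal(0, noise, len(y)), 0, 1)
    return pd.DataFrame({
        "curvedness_lo": lo, "curvedness_hi": lo + bin_width,
        "n_points": n_per_bin,
        "n_proximal": (y * n_per_bin).astype(int),
        "occupancy": y})


class TestFitSaturation:
    def test_recovers_constructed_breakpoint(self):
        fit = co.fit_saturation(ramp_profile(noise=0.01))
        assert abs(fit.breakpoint - 0.06) <= 0.004 + 1e-12
        assert fit.plateau == pytest.approx(0.95, abs=0.03)
        assert fit.slope == pytest.approx(15.0, rel=0.1)

    def test_flat_profile_breakpoint_at_range_start(self):
        prof = ramp_profile(slope=0.0, intercept=0.3)
        fit = co.fit_saturation(prof)
        assert abs(fit.slope) < 1e-6
        assert fit.plateau == pytest.approx(0.3)
        assert fit.breakpoint == pytest.approx(prof.curvedness_lo.iloc[0]
                                               + 0.002, abs=0.003)

    def test_strictly_linear_breakpoint_at_range_end(self):
        prof = ramp_profile(slope=8.0, intercept=0.0, breakpoint=1.0,
                            c_max=0.08)
        fit = co.fit_saturation(prof)
        assert fit.breakpoint >= prof.curvedness_hi.iloc[-2] - 1e-12

    def test_too_few_bins_raises(self):
        prof = ramp_profile().iloc[:4]
        with pytest.raises(ValueError, match="bins"):
            co.fit_saturation(prof)


class TestSaturationDiameter:
    def test_sphere_relation(self):
        # d = 2/C: 0.06 nm^-1 -> 33.3 nm, i.e. ~30 nm at one significant figure
        assert co.saturation_diameter_nm(0.06) == pytest.approx(33.333,
                                                                rel=1e-3)

    def test_invalid_breakpoint(self):
        with pytest.raises(ValueError):
            co.saturation_diameter_nm(0.0)
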