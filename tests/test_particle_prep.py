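import itertools

import numpy as np
import pandas as pd
import pytest

from memcurve import particle_prep as pp


def table(pos, normals=None, curvedness=None):
    pos = np.atleast_2d(pos).astype(float)
    df = pd.DataFrame(pos, columns=["x", "y", "z"])
    if normals is not None:
        normals = np.atleast_2d(normals).astype(float)
        df[["nx", "ny", "nz"]] = normals
    if curvedness is not None:
        df["curvedness"] = curvedness
    return df


class TestEnforceMinDistance:
    def test_pair_below_threshold_keeps_one(self):
        out = pp.enforce_min_distance(table([[0, 0, 0], [14, 0, 0]]), 15.0)
        assert len(out) == 1 and out.iloc[0].x == 0.0  # greedy: first wins

    def test_grid_at_spacing_20_all_kept(self):
        g = np.array(list(itertools.product(range(5), repeat=3))) * 20.0
        assert len(pp.enforce_min_distance(table(g), 15.0)) == len(g)

    def test_brute_force_pairwise_and_maximality(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 300, size=(5000, 3))
        kept = pp.enforce_min_distance(table(pts), 15.0)
        kp = kept[["x", "y", "z"]].to_numpy()
        d2 = ((kp[:, None] - kp[None, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= 15.0 ** 2
        # maximality: every input point is within 15 A of some kept point
        dall = ((pts[:, None] - kp[None, :]) ** 2).sum(-1).min(axis=1)
        assert np.sqrt(dall.max()) < 15.0

    def test_invariant_to_appending_duplicates(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, size=(100, 3))
        base = pp.enforce_min_distance(table(pts), 15.0)
        dup = pd.concat([table(pts), base], ignore_index=True)
        again = pp.enforce_min_distance(dup, 15.0)
        pd.testing.assert_frame_equal(base, again.iloc[:len(base)])
        assert len(again) == len(base)


class TestOrientationsFromNormals:
    def test_z_normal_gives_identity(self):
        out = pp.orientations_from_normals(table([[0, 0, 0]], [[0, 0, 1]]))
        r = pp.euler_to_matrix(out.iloc[0].rot, out.iloc[0].tilt,
                               out.iloc[0].psi)
        assert np.allclose(r, np.eye(3), atol=1e-12)

    def test_x_normal_round_trip(self):
        out = pp.orientations_from_normals(table([[0, 0, 0]], [[1, 0, 0]]))
        r = pp.euler_to_matrix(out.iloc[0].rot, out.iloc[0].tilt,
                               out.iloc[0].psi)
        assert np.allclose(r @ [0, 0, 1], [1, 0, 0], atol=1e-9)

    def test_random_normals_round_trip_property(self):
        rng = np.random.default_rng(3)
        n = rng.normal(size=(500, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        out = pp.orientations_from_normals(table(rng.uniform(0, 1, (500, 3)),
                                                 n))
        for i, row in enumerate(out.itertuples()):
            r = pp.euler_to_matrix(row.rot, row.tilt, row.psi)
            assert np.allclose(r @ [0, 0, 1], n[i], atol=1e-6)

    def test_zero_normal_raises_with_row(self):
        with pytest.raises(ValueError, match="rows"):
            pp.orientations_from_normals(table([[0, 0, 0]], [[0, 0, 0]]))

    def test_randomize_psi_reproducible(self):
        t = table(np.zeros((5, 3)), np.tile([0, 0, 1.0], (5, 1)))
        a = pp.orientations_from_normals(t, randomize_psi=True, seed=4)
        b = pp.orientations_from_normals(t, randomize_psi=True, seed=4)
        assert np.array_equal(a.psi, b.psi)
        assert a.psi.nunique() > 1


def kmeans_1d_dp(values, k):
    """Exact optimal 1-D k-means cost by dynamic programming."""
    x = np.sort(values)
    n = len(x)
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def cost(i, j):  # ssd of x[i:j]
        s, s2, m = pref[j] - pref[i], pref2[j] - pref2[i], j - i
        return s2 - s * s / m

    dp = np.full((k + 1, n + 1), np.inf)
    dp[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(1, n + 1):
            for i in range(kk - 1, j):
                c = dp[kk - 1, i] + cost(i, j)
                if c < dp[kk, j]:
                    dp[kk, j] = c
    return dp[k, n]


class TestClusterByCurvature:
    def test_well_separated_perfect_split(self):
        curv = np.array([0.02] * 30 + [0.06] * 20)
        out = pp.cluster_by_curvature(table(np.zeros((50, 3)),
                                            curvedness=curv), 2)
        assert (out.cluster_id[:30] == 0).all()
        assert (out.cluster_id[30:] == 1).all()

    def test_k1_single_cluster_grand_mean(self):
        rng = np.random.default_rng(0)
        curv = rng.uniform(0.02, 0.08, 40)
        out = pp.cluster_by_curvature(table(np.zeros((40, 3)),
                                            curvedness=curv), 1)
        assert out.cluster_id.nunique() == 1

    def test_matches_dp_optimum_cost(self):
        rng = np.random.default_rng(5)
        curv = rng.uniform(0.0, 1.0, 50)
        out = pp.cluster_by_curvature(table(np.zeros((50, 3)),
                                            curvedness=curv), 3, seed=0)
        got = sum(((curv[out.cluster_id == c]
                    - curv[out.cluster_id == c].mean()) ** 2).sum()
                  for c in range(3))
        assert got == pytest.approx(kmeans_1d_dp(curv, 3), rel=1e-6)

    def test_k_exceeding_distinct_values_warns(self):
        curv = np.array([0.02, 0.02, 0.06])
        with pytest.warns(UserWarning, match="distinct"):
            out = pp.cluster_by_curvature(table(np.zeros((3, 3)),
                                                curvedness=curv), 3)
        assert out.cluster_id.nunique() == 2


class TestFilterOrientationOutliers:
    def planar_patch(self, n_side=8, spacing=30.0):
        g = np.array(list(itertools.product(range(n_side), repeat=2)))
        pos = np.column_stack([g * spacing, np.zeros(len(g))])
        normals = np.tile([0.0, 0.0, 1.0], (len(g), 1))
        return pos, normals

    def test_flipped_normal_removed(self):
        pos, normals = self.planar_patch()
        normals[20] = [0, 0, -1]
        out = pp.filter_orientation_outliers(table(pos, normals))
        assert len(out) == len(pos) - 1

    def test_smooth_sphere_nothing_removed(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(400, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pos = v * 400.0
        out = pp.filter_orientation_outliers(table(pos, v), radius=100.0)
        assert len(out) == 400

    def test_isolated_point_retained_and_flagged(self):
        pos, normals = self.planar_patch()
        pos = np.vstack([pos, [5000.0, 5000.0, 0.0]])
        normals = np.vstack([normals, [1.0, 0.0, 0.0]])
        out = pp.filter_orientation_outliers(table(pos, normals))
        assert len(out) == len(pos)
        assert out.iloc[-1].flag == "isolated"

    def test_removed_fraction_tracks_injected_flips(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            g = np.array(list(itertools.product(range(12), repeat=2)))
            pos = np.column_stack([g * 30.0, np.zeros(len(g))])
            normals = np.tile([0.0, 0.0, 1.0], (len(g), 1))
            flip = rng.random(len(g)) < 0.05
            normals[flip] = [0.0, 0.0, -1.0]
            out = pp.filter_orientation_outliers(table(pos, normals))
            removed = (len(g) - len(out)) / len(g)
            assert removed <= flip.mean() + 0.01
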