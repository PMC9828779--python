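"""Procrustes alignment, size correction, and shape PCA."""

import numpy as np
import pytest
import scipy.linalg

from contactzone import morphometrics as mm
from contactzone.io_formats import LandmarkSet


def random_config(rng, k=23, spec_id="s"):
    return LandmarkSet(spec_id, rng.normal(0, 1, size=(k, 2)))


def similarity_transform(cfg, rng):
    ang = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    s = rng.uniform(0.5, 3.0)
    t = rng.uniform(-10, 10, size=2)
    return LandmarkSet(cfg.specimen_id + "_t", s * cfg.coords @ R.T + t)


class TestReflect:
    def test_negates_x_and_toggles_flag(self):
        c = LandmarkSet("a", [(1, 2)])
        r = mm.reflect_config(c)
        np.testing.assert_array_equal(r.coords, [[-1, 2]])
        assert r.flipped and not c.flipped

    def test_double_reflection_is_identity(self, rng):
        c = random_config(rng, 5)
        rr = mm.reflect_config(mm.reflect_config(c))
        np.testing.assert_array_equal(rr.coords, c.coords)
        assert rr.flipped == c.flipped

    def test_mirrored_wing_aligns_after_reflection(self, rng):
        """A mirror-image configuration is unreachable by rotation alone,
        but matches exactly once explicitly reflected."""
        left = random_config(rng, 23, "left")
        mirrored = LandmarkSet("right", left.coords * np.array([-1.0, 1.0]))
        res = mm.generalized_procrustes([left, mm.reflect_config(mirrored)])
        d = np.linalg.norm(res.aligned[0] - res.aligned[1])
        assert d < 1e-8


class TestGPA:
    def test_identical_configs_align_exactly(self, rng):
        c = random_config(rng)
        res = mm.generalized_procrustes(
            [c, LandmarkSet("b", c.coords.copy())])
        assert np.linalg.norm(res.aligned[0] - res.aligned[1]) < 1e-10
        assert res.converged

    def test_similarity_invariance(self, rng):
        c = random_config(rng)
        rot90 = np.array([[0.0, -1.0], [1.0, 0.0]])
        other = LandmarkSet("b", 2.0 * c.coords @ rot90.T + [5.0, -3.0])
        res = mm.generalized_procrustes([c, other])
        assert np.linalg.norm(res.aligned[0] - res.aligned[1]) < 1e-8

    def test_postconditions(self, rng):
        configs = [random_config(rng, 23, f"s{i}") for i in range(6)]
        res = mm.generalized_procrustes(configs)
        X = res.aligned.reshape(6, 23, 2)
        np.testing.assert_allclose(X.mean(axis=1), 0.0, atol=1e-9)
        assert np.sqrt((res.consensus ** 2).sum()) == pytest.approx(1.0)
        assert np.all(res.centroid_sizes > 0)

    def test_matches_independent_alternating_oracle(self, rng):
        """Summed squared residual to the consensus agrees with a naive
        alternating minimization built on scipy's orthogonal Procrustes."""
        configs = [random_config(rng, 23, f"s{i}") for i in range(5)]
        res = mm.generalized_procrustes(configs)
        X = res.aligned.reshape(5, 23, 2)
        rss = ((X - res.consensus) ** 2).sum()

        # oracle: same objective, independent implementation
        Y = []
        for c in configs:
            z = c.coords - c.coords.mean(axis=0)
            Y.append(z / np.sqrt((z ** 2).sum()))
        Y = np.array(Y)
        for _ in range(200):
            cons = Y.mean(axis=0)
            cons = cons - cons.mean(axis=0)
            cons = cons / np.sqrt((cons ** 2).sum())
            for i in range(5):
                R, _ = scipy.linalg.orthogonal_procrustes(Y[i], cons)
                if np.linalg.det(R) < 0:  # restrict to proper rotations
                    U, s, Vt = np.linalg.svd(Y[i].T @ cons)
                    R = U @ np.diag([1.0, -1.0]) @ Vt
                Y[i] = Y[i] @ R
        cons = Y.mean(axis=0)
        cons = cons - cons.mean(axis=0)
        cons /= np.sqrt((cons ** 2).sum())
        rss_oracle = ((Y - cons) ** 2).sum()
        assert rss == pytest.approx(rss_oracle, abs=1e-6)

    def test_invariant_to_nuisance_transforms(self, rng):
        configs = [random_config(rng, 11, f"s{i}") for i in range(8)]
        jittered = [similarity_transform(c, rng) for c in configs]
        a = mm.generalized_procrustes(configs)
        b = mm.generalized_procrustes(jittered)
        # shapes are identical, so Procrustes distances must agree
        da = np.linalg.norm(a.aligned - a.aligned[0], axis=1)
        db = np.linalg.norm(b.aligned - b.aligned[0], axis=1)
        np.testing.assert_allclose(da, db, atol=1e-6)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            mm.generalized_procrustes([random_config(rng)])
        with pytest.raises(ValueError, match="landmarks"):
            mm.generalized_procrustes([random_config(rng, 5),
                                       random_config(rng, 6)])
        degenerate = LandmarkSet("flat", np.ones((5, 2)))
        with pytest.raises(ValueError, match="flat"):
            mm.generalized_procrustes([degenerate, random_config(rng, 5)])


class TestWingLength:
    def test_three_four_five(self):
        coords = np.zeros((4, 2))
        coords[3] = [3, 4]
        assert mm.wing_length(LandmarkSet("a", coords)) == pytest.approx(5.0)

    def test_coincident_landmarks(self):
        c = LandmarkSet("a", np.zeros((4, 2)))
        assert mm.wing_length(c) == 0.0

    def test_invariant_to_reflection(self, rng):
        c = random_config(rng, 6)
        assert mm.wing_length(c, 1, 4) == pytest.approx(
            mm.wing_length(mm.reflect_config(c), 1, 4))

    def test_out_of_range(self, rng):
        with pytest.raises(IndexError):
            mm.wing_length(random_config(rng, 4), 1, 5)


class TestSizeCorrect:
    def test_exact_allometry_gives_zero_residuals(self, rng):
        size = rng.uniform(1, 2, size=10)
        traits = np.outer(size, [2.0, -3.0])
        resid = mm.size_correct(traits, size)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_independent_trait_is_centered(self, rng):
        size = rng.uniform(1, 2, size=50)
        traits = rng.normal(5, 1, size=(50, 1))
        resid = mm.size_correct(traits, size)
        assert abs(resid.mean()) < 1e-10
        assert abs((resid[:, 0] * (size - size.mean())).sum()) < 1e-8

    def test_matches_hand_ols(self):
        # 4 specimens, slope = 2, intercept = 1 by construction + noise col
        size = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([3.1, 4.9, 7.2, 8.8])
        xc = size - size.mean()
        beta = (xc * y).sum() / (xc ** 2).sum()
        expected = y - (y.mean() + beta * xc)
        resid = mm.size_correct(y[:, None], size)
        np.testing.assert_allclose(resid[:, 0], expected, atol=1e-12)

    def test_constant_size_rejected(self):
        with pytest.raises(ValueError):
            mm.size_correct(np.ones((5, 2)), np.ones(5))


class TestPCA:
    def test_collinear_points(self):
        t = np.linspace(0, 1, 20)
        X = np.column_stack([t, 2 * t])
        s = mm.pca(X)
        np.testing.assert_allclose(s.var_fraction, [1.0, 0.0], atol=1e-12)

    def test_isotropic_gaussian(self, rng):
        X = rng.normal(size=(10_000, 2))
        s = mm.pca(X)
        np.testing.assert_allclose(s.var_fraction, [0.5, 0.5], atol=0.02)

    def test_reconstruction_identity(self, rng):
        X = rng.normal(size=(30, 7))
        s = mm.pca(X)
        np.testing.assert_allclose(s.mean + s.scores @ s.loadings, X,
                                   atol=1e-9)

    def test_var_fraction_permutation_invariant(self, rng):
        X = rng.normal(size=(40, 5)) @ rng.normal(size=(5, 5))
        perm = rng.permutation(40)
        np.testing.assert_allclose(mm.pca(X).var_fraction,
                                   mm.pca(X[perm]).var_fraction, atol=1e-10)

    def test_loadings_unit_length_and_sign_convention(self, rng):
        X = rng.normal(size=(25, 4))
        s = mm.pca(X)
        np.testing.assert_allclose(np.linalg.norm(s.loadings, axis=1), 1.0)
        for row in s.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_size_correct_then_pca_pipeline_order(self, rng):
        size = rng.uniform(1, 3, size=40)
        X = np.outer(size, rng.normal(size=6)) + rng.normal(size=(40, 6))
        resid = mm.size_correct(X, size)
        np.testing.assert_allclose(mm.pca(resid).var_fraction,
                                   mm.pca(mm.size_correct(X, size)).var_fraction)

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError):
            mm.pca(np.ones((5, 3)))
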