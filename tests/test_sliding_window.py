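"""Sliding-window P-matrix scan: windowing, local filtering, trends."""

import numpy as np
import pytest

from contactzone import sliding_window as sw
from contactzone.sliding_window import WindowResult


class TestMakeWindows:
    def test_enumeration_n50(self):
        ids = list(range(1, 51))
        wins = sw.make_windows(ids, size=30, step=10)
        assert len(wins) == 3
        assert wins[0] == list(range(1, 31))
        assert wins[1] == list(range(11, 41))
        assert wins[2] == list(range(21, 51))

    def test_exactly_one_window(self):
        assert sw.make_windows(list(range(30)), 30, 10) == [list(range(30))]

    def test_n70_five_windows_partial_dropped(self):
        wins = sw.make_windows(list(range(1, 71)), 30, 10)
        assert len(wins) == 5
        assert wins[-1] == list(range(41, 71))

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            sw.make_windows(list(range(10)), 30, 10)

    def test_pure_function_of_ordering(self):
        ids = ["c", "a", "b", "e", "d", "f"]
        assert sw.make_windows(ids, 3, 2) == [["c", "a", "b"], ["b", "e", "d"]]


class TestLocalOutlierFilter:
    def test_retention_rate_matches_chi_square(self, rng):
        X = rng.multivariate_normal(np.zeros(3), np.diag([4.0, 2.0, 1.0]),
                                    size=10_000)
        kept = sw.local_outlier_filter(X, level=0.95)
        assert kept.mean() == pytest.approx(0.95, abs=0.01)

    def test_gross_outlier_removed(self, rng):
        X = rng.normal(size=(100, 4))
        X[0] = 50.0
        assert not sw.local_outlier_filter(X)[0]

    def test_near_idempotent(self, rng):
        X = rng.normal(size=(5000, 3))
        first = sw.local_outlier_filter(X)
        X2 = X[first]
        second = sw.local_outlier_filter(X2)
        assert 1.0 - second.mean() <= 0.06

    def test_too_few_specimens(self, rng):
        with pytest.raises(ValueError):
            sw.local_outlier_filter(rng.normal(size=(2, 3)))


def _scan_inputs(rng, n_per_species=90, d=4, rotate_near_contact=None):
    """Two species on a transect; optionally rotate p_max for the
    individuals of species A nearest the contact."""
    contact = 9.0
    base_cov = np.diag([8.0, 1.0, 0.5, 0.25])
    X_by, pos_by, ids_by = {}, {}, {}
    for sp, (lo, hi) in (("A", (0.0, contact)), ("B", (contact, 14.58))):
        pos = np.sort(rng.uniform(lo, hi, size=n_per_species))
        X = rng.multivariate_normal(np.zeros(d), base_cov, size=n_per_species)
        if rotate_near_contact and sp == "A":
            near = np.argsort(np.abs(pos - contact))[:30]
            ang = np.radians(rotate_near_contact)
            R = np.eye(d)
            R[0, 0] = R[1, 1] = np.cos(ang)
            R[0, 1], R[1, 0] = -np.sin(ang), np.sin(ang)
            X[near] = X[near] @ R.T
        X_by[sp], pos_by[sp] = X, pos
        ids_by[sp] = [f"{sp}{i}" for i in range(n_per_species)]
    return X_by, pos_by, ids_by, contact


class TestWindowScan:
    def test_null_false_positive_rate(self):
        """All windows from one multivariate normal: about 5% of windows
        should be flagged at the dual-95th-percentile criterion."""
        flags, total = 0, 0
        for rep in range(12):
            rng = np.random.default_rng(100 + rep)
            X_by, pos_by, ids_by, contact = _scan_inputs(rng)
            res = sw.window_scan(X_by, pos_by, ids_by, contact,
                                 size=30, step=10, n_boot=300, seed=rep)
            flags += sum(r.significant_theta for r in res)
            total += len(res)
        assert flags / total < 0.20

    def test_rotation_near_contact_detected(self):
        hits_near, hits_far = 0, 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(200 + rep)
            X_by, pos_by, ids_by, contact = _scan_inputs(
                rng, rotate_near_contact=60.0)
            res = sw.window_scan(X_by, pos_by, ids_by, contact,
                                 size=30, step=10, n_boot=400, seed=rep)
            resA = [r for r in res if r.species == "A"]
            hits_near += resA[0].significant_theta
            hits_far += resA[-1].significant_theta
        assert hits_near >= int(0.9 * n_rep)
        assert hits_far < hits_near

    def test_reference_disjoint_from_windows(self, rng):
        X_by, pos_by, ids_by, contact = _scan_inputs(rng)
        res = sw.window_scan(X_by, pos_by, ids_by, contact, size=30,
                             step=10, n_boot=200, seed=0)
        for sp in ("A", "B"):
            pos = pos_by[sp]
            order = np.argsort(np.abs(pos - contact))
            ref_ids = {ids_by[sp][i] for i in order[-30:]}
            for r in res:
                if r.species == sp:
                    assert not (set(r.member_ids) & ref_ids)

    def test_bit_reproducible(self, rng):
        X_by, pos_by, ids_by, contact = _scan_inputs(rng)
        a = sw.window_scan(X_by, pos_by, ids_by, contact, n_boot=200, seed=5)
        b = sw.window_scan(X_by, pos_by, ids_by, contact, n_boot=200, seed=5)
        for ra, rb in zip(a, b):
            assert ra == rb

    def test_window_ordering_away_from_contact(self, rng):
        X_by, pos_by, ids_by, contact = _scan_inputs(rng)
        res = sw.window_scan(X_by, pos_by, ids_by, contact, n_boot=200, seed=1)
        for sp in ("A", "B"):
            dists = [abs(r.mean_distance_km - contact)
                     for r in res if r.species == sp]
            assert all(np.diff(dists) > 0)


def _fake_results(theta_by_species, contact=9.0):
    out = []
    for sp, thetas in theta_by_species.items():
        for i, t in enumerate(thetas):
            out.append(WindowResult(
                species=sp, window_index=i, member_ids=[],
                mean_distance_km=contact + (1 + i) * (1 if sp == "B" else -1),
                theta_deg=float(t), matrix_distance=float(t) / 10.0,
                significant_theta=False, significant_distance=False,
                p_theta=0.5, p_distance=0.5))
    return out


class TestTrendTest:
    def test_flat_series_no_interaction(self, rng):
        res = _fake_results({"A": 10 + rng.normal(0, 0.5, 8),
                             "B": 10 + rng.normal(0, 0.5, 8)})
        table = sw.trend_test(res, "theta")
        assert table.loc["distance:species", "p_value"] > 0.05

    def test_one_species_trend_detected(self, rng):
        thetasA = np.linspace(0, 30, 8) + rng.normal(0, 2.0, 8)
        thetasB = 10 + rng.normal(0, 2.0, 8)
        res = _fake_results({"A": thetasA, "B": thetasB})
        table = sw.trend_test(res, "theta")
        assert table.loc["distance:species", "p_value"] < 0.01

    def test_doubling_distances_halves_slope(self, rng):
        res = _fake_results({"A": np.linspace(5, 25, 6),
                             "B": np.linspace(8, 20, 6)})
        t1 = sw.trend_test(res, "theta")
        for r in res:
            r.mean_distance_km *= 2.0
        t2 = sw.trend_test(res, "theta")
        assert t2.loc["distance", "coef"] == pytest.approx(
            t1.loc["distance", "coef"] / 2.0, rel=1e-8)

    def test_needs_three_windows_per_species(self, rng):
        res = _fake_results({"A": [1, 2], "B": [1, 2, 3]})
        with pytest.raises(ValueError):
            sw.trend_test(res)
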