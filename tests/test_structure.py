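import itertools

import numpy as np
import pytest

from csac import DEFAULT_PARAMS
from csac.fixtures import dense_ball, rod, two_family
from csac.model import Conformation, WeightedEnsemble
from csac.structure import (classify_compactness, classify_substructures,
                            cluster_ensemble, compactness_thresholds,
                            distance_matrix, find_substructures,
                            minimal_enclosing_sphere, substructure_summary)

LP = DEFAULT_PARAMS.persistence_length_nm


def exhaustive_mes(points):
    """Oracle: best ball among all <=4-point support candidates."""
    n = len(points)
    best = (None, np.inf)
    from csac.structure import _ball_of
    for k in (1, 2, 3, 4):
        for idx in itertools.combinations(range(n), k):
            c, r = _ball_of([points[i] for i in idx])
            if r < 0:
                continue
            d = np.linalg.norm(points - c, axis=1).max()
            if d <= r + 1e-9 and r < best[1]:
                best = (c, r)
    return best


class TestMinimalEnclosingSphere:
    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(15):
            pts = rng.normal(0, 100, size=(rng.integers(2, 14), 3))
            c, r = minimal_enclosing_sphere(pts)
            co, ro = exhaustive_mes(pts)
            assert r == pytest.approx(ro, rel=1e-9, abs=1e-9)
            assert np.linalg.norm(pts - c, axis=1).max() <= r + 1e-6

    def test_collinear_points(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [30, 0, 0.0]])
        c, r = minimal_enclosing_sphere(pts)
        assert r == pytest.approx(15.0, abs=1e-9)
        assert c == pytest.approx([15.0, 0, 0], abs=1e-9)

    def test_single_and_duplicate_points(self):
        c, r = minimal_enclosing_sphere(np.array([[1.0, 2, 3]]))
        assert r == 0.0
        c, r = minimal_enclosing_sphere(np.array([[1.0, 2, 3]] * 5))
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_shuffle_invariant(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 50, size=(30, 3))
        r1 = minimal_enclosing_sphere(pts, seed=0)[1]
        r2 = minimal_enclosing_sphere(pts, seed=99)[1]
        assert r1 == pytest.approx(r2, rel=1e-9)


class TestDistanceMatrix:
    def test_rod_units_exact(self):
        m = distance_matrix(rod(12), resolution="units")
        i, j = np.indices(m.shape)
        assert np.allclose(m, np.abs(i - j) * LP)

    def test_symmetry_and_diagonal(self, one_confined_chain):
        m = distance_matrix(one_confined_chain)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)

    def test_matches_brute_force(self, one_confined_chain):
        m = distance_matrix(one_confined_chain, resolution="units")
        u = one_confined_chain.unit_coordinates
        brute = np.linalg.norm(u[:, None] - u[None, :], axis=2)
        assert np.allclose(m, brute, atol=1e-12)


class TestClustering:
    def test_two_families_separate_perfectly(self):
        confs, labels = two_family(12, 12, n_units=40, seed=3)
        ens = WeightedEnsemble(confs, 40, None, DEFAULT_PARAMS)
        ca = cluster_ensemble(ens, n_clusters=2, fit_alpha=False)
        rods = set(ca.labels[np.array(labels) == "rod"])
        balls = set(ca.labels[np.array(labels) == "ball"])
        assert rods.isdisjoint(balls)
        assert len(rods) == len(balls) == 1

    def test_identical_chains_cluster_cleanly(self):
        confs = [rod(30) for _ in range(10)]
        ens = WeightedEnsemble(confs, 30, None, DEFAULT_PARAMS)
        ca = cluster_ensemble(ens, n_clusters=2, fit_alpha=False)
        assert len(ca.labels) == 10

    def test_too_many_clusters_rejected(self, small_confined_ensemble):
        with pytest.raises(ValueError):
            cluster_ensemble(small_confined_ensemble, n_clusters=1000)

    def test_per_cluster_alpha_fitted(self, small_confined_ensemble):
        ca = cluster_ensemble(small_confined_ensemble, n_clusters=3,
                              fit_range=(2, 30))
        assert len(ca.per_cluster_alpha) >= 1
        for fit in ca.per_cluster_alpha.values():
            assert np.isfinite(fit.exponent)


class TestCompactness:
    def test_rods_open_balls_compact(self):
        confs, labels = two_family(10, 10, n_units=40, seed=1)
        ens = WeightedEnsemble(confs, 40, None, DEFAULT_PARAMS)
        # rods sit at rod-normalized Rg ~ 1, dense balls far below 0.2
        frac = classify_compactness(ens, (0.2, 0.8))
        assert frac["open"] == pytest.approx(0.5)
        assert frac["compact"] == pytest.approx(0.5)
        rod_ens = WeightedEnsemble(confs[:10], 40, None, DEFAULT_PARAMS)
        ball_ens = WeightedEnsemble(confs[10:], 40, None, DEFAULT_PARAMS)
        assert classify_compactness(rod_ens, (0.2, 0.8))["open"] == pytest.approx(1.0)
        assert classify_compactness(ball_ens, (0.2, 0.8))["compact"] == pytest.approx(1.0)

    def test_threshold_helper_spans_distribution(self):
        confs, _ = two_family(10, 10, n_units=40, seed=1)
        ens = WeightedEnsemble(confs, 40, None, DEFAULT_PARAMS)
        lo, hi = compactness_thresholds([ens], quantiles=(0.2, 0.8))
        assert 0 < lo < hi

    def test_fractions_sum_to_one(self, small_confined_ensemble):
        frac = classify_compactness(small_confined_ensemble, (0.05, 0.4))
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_bad_thresholds_rejected(self, small_confined_ensemble):
        with pytest.raises(ValueError):
            classify_compactness(small_confined_ensemble, (0.5, 0.2))


def ball_with_tails(ball_units=40, tail_units=30):
    """A dense ball flanked by two straight rods, as one chain."""
    p = DEFAULT_PARAMS
    ball = dense_ball(ball_units, p)
    bpu = p.beads_per_unit
    d = p.bead_diameter_nm
    first, last = ball.coordinates[0], ball.coordinates[-1]
    n_tail = tail_units * bpu
    pre = first + np.outer(np.arange(n_tail, 0, -1) * d, [0, 0, -1.0]) \
        - [0, 0, 0]
    pre = first - np.outer(np.arange(n_tail, 0, -1) * d, [0, 0, 1.0])
    post = last + np.outer(np.arange(1, n_tail + 1) * d, [0, 0, 1.0])
    coords = np.vstack([pre, ball.coordinates, post])
    n_units = (len(coords) + bpu - 1) // bpu
    return Conformation(coordinates=coords, n_units=n_units, log_weight=0.0,
                        confinement_diameter_um=None, seed=0, params=p)


class TestSubstructures:
    def test_rod_has_none(self):
        assert find_substructures(rod(250)) == []

    def test_ball_with_tails_yields_one(self):
        conf = ball_with_tails()
        subs = find_substructures(conf)
        assert len(subs) == 1
        s = subs[0]
        # the detected interval covers the ball (which sits between the tails)
        a, e = s.bead_interval
        n_tail = 30 * 5
        assert a <= n_tail and e >= n_tail + 196
        assert s.dna_kbp > 400.0

    def test_intervals_disjoint_and_bounded(self, one_confined_chain):
        subs = find_substructures(one_confined_chain)
        ends = 0
        for s in subs:
            a, e = s.bead_interval
            assert a >= ends and e <= one_confined_chain.n_beads
            ends = e
        cover = sum(s.n_beads for s in subs)
        assert cover <= one_confined_chain.n_beads

    def test_dna_threshold_respected(self, one_confined_chain):
        for s in find_substructures(one_confined_chain, min_kbp=400.0):
            assert s.dna_kbp > 400.0


def two_balls_chain(face_gap_nm):
    """Two dense balls, sequence-separated by a long detour but spatially
    ``face_gap_nm`` apart (the detour parks far away in +z)."""
    p = DEFAULT_PARAMS
    b1 = dense_ball(40, p).coordinates
    d = p.bead_diameter_nm
    bridge = np.zeros((300, 3))
    bridge[:, 2] = 3000.0
    bridge[:, 0] = np.arange(300) * d
    b2 = b1 + [np.ptp(b1[:, 0]) + d + face_gap_nm, 0, 0]
    coords = np.vstack([b1, bridge, b2])
    n_units = (len(coords) + p.beads_per_unit - 1) // p.beads_per_unit
    return Conformation(coords, n_units, 0.0, None, 0, p)


class TestClassifySubstructures:
    def test_far_separated_balls_independent(self):
        conf = two_balls_chain(5000.0)
        subs = find_substructures(conf)
        assert len(subs) == 2
        out = classify_substructures(subs, conf)
        assert all(s.category == "independent" for s in out)
        assert all(s.strictly_isolated for s in out)

    def test_nearby_balls_interactive(self):
        # 20 nm face gap: bead centres across the interface are within the
        # 60 nm contact radius for a large share of units
        conf = two_balls_chain(20.0)
        subs = find_substructures(conf)
        assert len(subs) == 2
        out = classify_substructures(subs, conf)
        assert all(s.category == "interactive" for s in out)

    def test_order_invariance(self):
        conf = two_balls_chain(20.0)
        subs = find_substructures(conf)
        fwd = classify_substructures(subs, conf)
        rev = classify_substructures(list(reversed(subs)), conf)
        assert {s.bead_interval: s.category for s in fwd} == \
            {s.bead_interval: s.category for s in rev}

    def test_shrinking_radius_never_creates_interaction(self):
        conf = two_balls_chain(20.0)
        subs = find_substructures(conf)
        wide = classify_substructures(subs, conf, r_c=120.0)
        narrow = classify_substructures(subs, conf, r_c=10.0)
        for w, n in zip(wide, narrow):
            assert n.interaction_fraction <= w.interaction_fraction

    def test_single_substructure_independent(self):
        conf = ball_with_tails()
        subs = find_substructures(conf)
        out = classify_substructures(subs, conf)
        assert out[0].category == "independent"
        assert out[0].interaction_fraction == 0.0


def test_summary_reports_weighted_statistics(small_confined_ensemble):
    s = substructure_summary(small_confined_ensemble)
    assert s["mean_substructures_per_chain"] >= 0.0
    assert 0.0 <= s["mean_coverage_fraction"] <= 1.0
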