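import itertools
import math

import numpy as np
import pytest

from csac import (DEFAULT_PARAMS, CandidateSet, check_confinement,
                  check_self_avoidance, feasible_moves, grow_chain,
                  grow_ensemble, make_candidate_set)
from csac.growth import GrowthError, _r_allow_nm
from csac.model import DISTANCE_TOL


class TestCandidateSet:
    def test_unit_vectors(self):
        cs = make_candidate_set(100)
        assert np.allclose(np.linalg.norm(cs.directions, axis=1), 1.0)

    def test_isotropy_k2(self):
        cs = make_candidate_set(2)
        assert np.linalg.norm(cs.directions.mean(axis=0)) < 0.5

    def test_isotropy_k100(self):
        cs = make_candidate_set(100)
        assert np.linalg.norm(cs.directions.mean(axis=0)) < 0.05

    def test_rotation_preserves_angles(self):
        a = make_candidate_set(40, seed=1).directions
        b = make_candidate_set(40, seed=2).directions
        assert not np.allclose(a, b)
        ga = np.sort((a @ a.T).round(9).ravel())
        gb = np.sort((b @ b.T).round(9).ravel())
        assert np.allclose(ga, gb, atol=1e-7)

    def test_rejects_non_unit(self):
        with pytest.raises(ValueError):
            CandidateSet(directions=np.array([[2.0, 0, 0], [0, 1, 0]]))


def brute_feasible(coords, dirs, d_um, params):
    """All-pairs, all-interpolated-beads oracle for candidate feasibility."""
    seg = params.bead_diameter_nm
    bpu = params.beads_per_unit
    r_allow = _r_allow_nm(d_um, params)
    end = coords[-1]
    out = []
    for c, u in enumerate(dirs):
        beads = end + np.outer(np.arange(1, bpu + 1) * seg, u)
        if np.isfinite(r_allow) and np.any(
                np.linalg.norm(beads, axis=1) > r_allow):
            continue
        d = np.linalg.norm(beads[:, None, :] - coords[None, :, :], axis=2)
        if (d < seg - DISTANCE_TOL).any():
            continue
        out.append(c)
    return np.array(out, int)


class TestFeasibleMoves:
    def test_matches_brute_oracle(self):
        rng = np.random.default_rng(0)
        cs = make_candidate_set(60, seed=9, mode="fixed_global")
        for trial in range(12):
            d_um = [None, 1.5, 0.8][trial % 3]
            conf, _ = grow_chain(int(rng.integers(5, 40)), d_um,
                                 seed=int(rng.integers(1 << 30)))
            if conf is None:
                continue
            got = feasible_moves(conf, cs, d_um)
            want = brute_feasible(conf.coordinates, cs.directions, d_um,
                                  DEFAULT_PARAMS)
            assert np.array_equal(got, want)

    def test_all_feasible_from_center(self):
        coords = np.zeros((1, 3))
        cs = make_candidate_set(100, seed=3, mode="fixed_global")
        assert len(feasible_moves(coords, cs, 1.5)) == 100

    def test_outward_moves_blocked_near_boundary(self):
        # a seed bead close to the wall cannot grow a unit pointing outward
        params = DEFAULT_PARAMS
        r_allow = _r_allow_nm(1.5, params)
        coords = np.array([[r_allow - params.persistence_length_nm / 2, 0, 0]])
        cs = make_candidate_set(100, seed=3, mode="fixed_global")
        feas = feasible_moves(coords, cs, 1.5)
        assert 0 < len(feas) < 100
        assert np.array_equal(feas,
                              brute_feasible(coords, cs.directions, 1.5, params))


class TestGrowChain:
    def test_deterministic(self):
        a, _ = grow_chain(20, 1.5, seed=5)
        b, _ = grow_chain(20, 1.5, seed=5)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.log_weight == b.log_weight

    def test_free_two_units_weight_one(self):
        conf, rec = grow_chain(2, None, seed=3)
        assert conf.weight == pytest.approx(1.0)
        assert rec.final_status == "completed"

    def test_weight_in_unit_interval(self, small_confined_ensemble):
        assert all(c.log_weight <= 0 for c in small_confined_ensemble)

    def test_invalid_n_units(self):
        with pytest.raises(ValueError):
            grow_chain(1, None, seed=0)

    def test_dead_end_is_normal_outcome(self):
        # a sphere barely wider than one unit forces frequent dead ends
        outcomes = set()
        for s in range(30):
            conf, rec = grow_chain(40, 0.35, seed=s)
            outcomes.add(rec.final_status)
            if conf is None:
                assert rec.final_status == "dead_end"
                assert rec.m_counts[rec.steps_completed] == 0
        assert "dead_end" in outcomes


class TestGrowEnsemble:
    def test_exact_chain_count_and_validity(self, small_confined_ensemble):
        assert len(small_confined_ensemble) == 60
        for conf in small_confined_ensemble:
            assert check_self_avoidance(conf)[0]
            assert check_confinement(conf, 1.5)

    def test_reproducible_from_master_seed(self):
        a = grow_ensemble(5, 30, 1.5, seed=99)
        b = grow_ensemble(5, 30, 1.5, seed=99)
        for x, y in zip(a, b):
            assert np.array_equal(x.coordinates, y.coordinates)

    def test_different_seeds_differ(self):
        a = grow_ensemble(3, 30, None, seed=1)
        b = grow_ensemble(3, 30, None, seed=2)
        assert not np.array_equal(a.conformations[0].coordinates,
                                  b.conformations[0].coordinates)

    def test_attrition_rises_under_tighter_confinement(self):
        loose = grow_ensemble(15, 60, 1.5, seed=7)
        tight = grow_ensemble(15, 60, 0.55, seed=7)
        assert tight.attrition_count >= loose.attrition_count

    def test_attrition_ceiling_aborts(self):
        with pytest.raises(GrowthError):
            grow_ensemble(5, 500, 0.25, seed=1, max_attrition=0.01)


class TestWeightedDistribution:
    """The defining property of the sampler: importance weights recover the
    uniform distribution over realizable chains."""

    def lattice_candidates(self):
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                         [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        return CandidateSet(directions=dirs, generation_mode="fixed_global")

    def enumerate_saws(self, n_steps):
        """All vertex-self-avoiding n-step paths on the cubic lattice."""
        dirs = self.lattice_candidates().directions
        paths = []
        for seq in itertools.product(range(6), repeat=n_steps):
            pos = [(0.0, 0.0, 0.0)]
            ok = True
            for c in seq:
                nxt = tuple(np.array(pos[-1]) + dirs[c])
                if nxt in pos:
                    ok = False
                    break
                pos.append(nxt)
            if ok:
                paths.append(seq)
        return paths

    def test_weighted_frequencies_match_uniform_enumeration(self):
        # 4 growth steps: closed-loop exclusions make the weights nontrivial
        n_units = 5
        paths = self.enumerate_saws(n_units - 1)
        # oracle distribution of squared end-to-end distance (lattice units)
        dirs = self.lattice_candidates().directions
        def r2_of(seq):
            return int(round(np.linalg.norm(dirs[list(seq)].sum(axis=0)) ** 2))
        oracle = {}
        for seq in paths:
            oracle[r2_of(seq)] = oracle.get(r2_of(seq), 0) + 1
        oracle = {k: v / len(paths) for k, v in oracle.items()}

        cs = self.lattice_candidates()
        lp = DEFAULT_PARAMS.persistence_length_nm
        hits = {}
        tot = 0.0
        for seed in range(10000):
            conf, _ = grow_chain(n_units, None, seed=seed, candidates=cs)
            assert conf is not None  # dead ends impossible in 4 lattice steps
            u = conf.unit_coordinates
            r2 = int(round(np.linalg.norm(u[-1] - u[0]) ** 2 / lp ** 2))
            w = conf.weight
            hits[r2] = hits.get(r2, 0.0) + w
            tot += w
        for k, p in oracle.items():
            # Monte-Carlo tolerance: well within 5 sigma at n = 10,000
            assert abs(hits.get(k, 0.0) / tot - p) < 0.012, \
                f"R2={k}: weighted {hits.get(k, 0)/tot:.4f} vs uniform {p:.4f}"
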