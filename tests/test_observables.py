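import numpy as np
import pytest

from csac import DEFAULT_PARAMS, grow_ensemble
from csac.fixtures import hairpin, rod
from csac.model import WeightedEnsemble
from csac.observables import (contact_probability, default_s_grid,
                              end_contact_probability, end_contact_with_error,
                              end_to_end, end_to_end_with_error, msd_profile,
                              per_chain_contact_matrix, weighted_mean)

LP = DEFAULT_PARAMS.persistence_length_nm


def one_chain_ensemble(conf):
    return WeightedEnsemble([conf], conf.n_units, None, conf.params)


class TestWeightedMean:
    def test_uniform_weights(self):
        assert weighted_mean([1, 2, 3], [1, 1, 1]) == pytest.approx(2.0)

    def test_zero_weight_excluded(self):
        assert weighted_mean([1, 2], [0, 5]) == pytest.approx(2.0)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=50)
        w = rng.random(50)
        assert weighted_mean(v, w) == pytest.approx(
            (w * v).sum() / w.sum(), rel=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean([1.0], [0.0])

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean([1.0, 2.0], [1.0, -1.0])


class TestMsdProfile:
    def test_rigid_rod_exact(self):
        ens = one_chain_ensemble(rod(40))
        prof = msd_profile(ens, s_values=[1, 2, 5, 10, 39])
        assert np.allclose(prof.R2_values,
                           (prof.s_values * LP) ** 2, rtol=1e-12)

    def test_two_chain_hand_weights(self):
        # rod (weight e^0) and hairpin (weight e^-1): hand-computed average
        r = rod(10)
        h = hairpin(4)
        h.log_weight = -1.0
        h.coordinates = h.coordinates[:r.n_beads]  # match lengths: 46 beads
        ens = WeightedEnsemble([r, h], 10, None, r.params)
        prof = msd_profile(ens, s_values=[2])
        wr, wh = 1.0, np.exp(-1.0)

        def mean_r2(conf, s=2):
            u = conf.coordinates[::5][:10]
            d = u[s:] - u[:-s]
            return ((d ** 2).sum(axis=1)).mean()

        expected = (wr * mean_r2(r) + wh * mean_r2(h)) / (wr + wh)
        assert prof.R2_values[0] == pytest.approx(expected, rel=1e-12)

    def test_contour_bound(self, small_confined_ensemble):
        prof = msd_profile(small_confined_ensemble, s_values=[1, 3, 10, 30])
        assert np.all(prof.R2_values <= (prof.s_values * LP) ** 2 + 1e-6)

    def test_invalid_s_rejected(self, small_confined_ensemble):
        with pytest.raises(ValueError):
            msd_profile(small_confined_ensemble, s_values=[0])


class TestEndToEnd:
    def test_rod_exact(self):
        assert end_to_end(one_chain_ensemble(rod(25))) == \
            pytest.approx(24 * LP)

    def test_confined_plateau_below_sphere(self, small_confined_ensemble):
        d_nm = 1.5e3 - DEFAULT_PARAMS.bead_diameter_nm
        assert end_to_end(small_confined_ensemble) <= d_nm

    def test_error_estimate_positive(self, small_free_ensemble):
        m, se = end_to_end_with_error(small_free_ensemble)
        assert m > 0 and 0 < se < m


class TestContactProbability:
    def test_rigid_rod_no_contacts(self):
        ens = one_chain_ensemble(rod(40))
        prof = contact_probability([ens], [1, 2, 5, 10])
        assert np.all(prof.Pc_values == 0.0)

    def test_adjacent_units_never_in_default_contact(self, small_confined_ensemble):
        # boundary beads of adjacent units sit exactly L_p = 150 nm apart,
        # beyond the 60 nm default contact radius
        prof = contact_probability([small_confined_ensemble], [1])
        assert prof.Pc_values[0] == 0.0

    def test_monotone_in_contact_radius(self, small_confined_ensemble):
        s = [2, 5, 10, 20]
        p1 = contact_probability([small_confined_ensemble], s, r_c=60.0)
        p2 = contact_probability([small_confined_ensemble], s, r_c=120.0)
        assert np.all(p2.Pc_values >= p1.Pc_values)

    def test_pools_only_reachable_ensembles(self):
        a = grow_ensemble(10, 20, None, seed=1)
        b = grow_ensemble(10, 60, None, seed=2)
        prof = contact_probability([a, b], [10, 30], r_c=300.0)
        assert prof.n_effective[1] < prof.n_effective[0]

    def test_unreachable_s_rejected(self):
        a = grow_ensemble(5, 20, None, seed=1)
        with pytest.raises(ValueError):
            contact_probability([a], [25])

    def test_matrix_matches_brute_force(self, small_confined_ensemble):
        s = np.array([3, 7])
        mat = per_chain_contact_matrix(small_confined_ensemble, s, r_c=60.0)
        conf = small_confined_ensemble.conformations[0]
        u = conf.unit_coordinates
        for j, sv in enumerate(s):
            hits = [np.linalg.norm(u[i + sv] - u[i]) <= 60.0
                    for i in range(len(u) - sv)]
            assert mat[0, j] == pytest.approx(np.mean(hits))


class TestEndContactClosure:
    def test_rod_has_no_end_contact(self):
        n, pc = end_contact_probability(one_chain_ensemble(rod(30)),
                                        r_c=300.0, method="indicator")
        assert (n, pc) == (30, 0.0)

    def test_closure_consistent_with_indicator(self):
        # the one-step look-ahead at length N must agree with the direct
        # indicator estimate at length N+1 (both estimate the same number)
        r_c = 450.0
        base = grow_ensemble(1500, 14, None, seed=31)
        longer = grow_ensemble(3000, 15, None, seed=32)
        n1, pc_cl, se_cl = end_contact_with_error(base, r_c=r_c, seed=1)
        n2, pc_ind = end_contact_probability(longer, r_c=r_c,
                                             method="indicator")
        assert n1 == n2 == 15
        w = longer.normalized_weights()
        hits = np.array([np.linalg.norm(c.coordinates[-1] - c.coordinates[0])
                         <= r_c for c in longer], float)
        se_ind = np.sqrt(float(w @ (hits - pc_ind) ** 2)
                         / longer.effective_sample_size())
        assert pc_cl == pytest.approx(pc_ind,
                                      abs=4 * np.hypot(se_cl, se_ind))


class TestWeightedMeanProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.tuples(st.floats(-1e6, 1e6), st.floats(0.0, 1e3)),
                    min_size=1, max_size=40).filter(
                        lambda vw: sum(w for _, w in vw) > 0))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_bounded_by_extremes_and_scale_invariant(self, vw):
        v = [x for x, _ in vw]
        w = [x for _, x in vw]
        m = weighted_mean(v, w)
        assert min(v) - 1e-9 <= m <= max(v) + 1e-9
        assert weighted_mean(v, [2.0 * x for x in w]) == pytest.approx(
            m, rel=1e-9, abs=1e-9)
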