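"""Matching methods: hand-computed cases, conservation, exhaustive oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from attmatch import (
    GAConfig,
    StudyData,
    effective_sample_size,
    gen_mahalanobis,
    generate_dataset,
    match_full,
    match_genetic,
    match_greedy_nn,
    match_none,
    match_optimal,
    match_subclassification,
    weights_iptw_att,
)
from attmatch.nuisance import fit_propensity_parametric


def study_from_ps(ps_treated, ps_control, seed=0):
    """A study whose 'propensity' is handed in directly as a vector."""
    nt, nc = len(ps_treated), len(ps_control)
    rng = np.random.default_rng(seed)
    ps = np.concatenate([np.asarray(ps_treated, float), np.asarray(ps_control, float)])
    data = StudyData(
        covariates=pd.DataFrame({"X": rng.normal(size=nt + nc)}),
        treatment=np.concatenate([np.ones(nt, int), np.zeros(nc, int)]),
        outcome=rng.normal(size=nt + nc),
    )
    return data, ps


class TestNone:
    def test_all_weights_one_and_ess_raw(self):
        data, _ = study_from_ps([0.5, 0.6], [0.4, 0.3, 0.2])
        m = match_none(data)
        assert np.array_equal(m.weights, np.ones(5))
        assert m.ess_treated == 2
        assert m.ess_control == 3


class TestGreedyNN:
    def test_single_control_used_twice(self):
        data, ps = study_from_ps([0.4, 0.5], [0.45])
        m = match_greedy_nn(data, ps)
        assert m.weights[2] == pytest.approx(2.0)

    def test_tie_goes_to_lowest_index(self):
        # both controls at distance exactly 0.25 from the treated unit
        data, ps = study_from_ps([0.25], [0.0, 0.5])
        m = match_greedy_nn(data, ps)
        assert m.weights[1] == pytest.approx(1.0)
        assert m.weights[2] == 0.0

    def test_exact_clones_zero_ps_gap(self):
        data, ps = study_from_ps([0.2, 0.7], [0.2, 0.7])
        m = match_greedy_nn(data, ps)
        pt = ps[data.treatment == 1]
        wc = m.weights[data.treatment == 0]
        mc = np.average(ps[data.treatment == 0], weights=wc)
        assert mc == pytest.approx(pt.mean())


class TestOptimal:
    def test_hand_case_beats_alternative_assignment(self):
        data, ps = study_from_ps([0.4, 0.5], [0.45, 0.6])
        m = match_optimal(data, ps)
        assert m.extra["total_distance"] == pytest.approx(0.15)
        # pairs: 0.4-0.45 and 0.5-0.6
        assert m.weights[2] == 1.0 and m.weights[3] == 1.0

    def test_single_treated_reduces_to_nn(self):
        data, ps = study_from_ps([0.42], [0.1, 0.44, 0.9])
        m = match_optimal(data, ps)
        assert m.weights[2] == 1.0
        assert m.weights[1] == m.weights[3] == 0.0

    def test_infeasible_when_fewer_controls(self):
        data, ps = study_from_ps([0.4, 0.5, 0.6], [0.45])
        with pytest.raises(ValueError, match="infeasible"):
            match_optimal(data, ps)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(60):
            nt = int(rng.integers(1, 6))
            nc = int(rng.integers(nt, 8))
            pt = rng.uniform(size=nt)
            pc = rng.uniform(size=nc)
            data, ps = study_from_ps(pt, pc, seed=int(rng.integers(2**31)))
            got = match_optimal(data, ps).extra["total_distance"]
            best = min(
                sum(abs(pt[i] - pc[perm[i]]) for i in range(nt))
                for perm in itertools.permutations(range(nc), nt)
            )
            assert got == pytest.approx(best, abs=1e-12)


class TestSubclassification:
    def test_two_subclasses_one_control_each(self):
        data, ps = study_from_ps([0.2, 0.8], [0.1, 0.9], seed=1)
        m = match_subclassification(data, ps, n_subclasses=2)
        assert m.weights[2] == pytest.approx(1.0)
        assert m.weights[3] == pytest.approx(1.0)

    def test_uniform_controls_get_equal_weights(self):
        pt = np.linspace(0.1, 0.9, 20)
        pc = np.linspace(0.1, 0.9, 40)
        data, ps = study_from_ps(pt, pc, seed=2)
        m = match_subclassification(data, ps, n_subclasses=4)
        wc = m.weights[data.treatment == 0]
        assert np.allclose(wc, wc[0])

    def test_empty_subclass_merged_conserving_weight(self):
        # controls only at the low end: upper subclasses have none
        pt = [0.1, 0.2, 0.7, 0.8]
        pc = [0.1, 0.15, 0.2]
        data, ps = study_from_ps(pt, pc, seed=3)
        m = match_subclassification(data, ps, n_subclasses=2)
        assert m.weights[data.treatment == 0].sum() == pytest.approx(4.0)


def _star_partition_oracle(pt, pc):
    """Exhaustive minimum over star partitions (each set: 1 treated + >=1
    controls, or >=1 treated + 1 control) of total within-set distance."""
    nt, nc = len(pt), len(pc)

    def rec(ts, cs):
        # ts, cs: tuples of remaining treated/control indices
        if not ts:
            return 0.0 if not cs else np.inf
        t0, rest = ts[0], ts[1:]
        best = np.inf
        # t0 is a centre taking a nonempty subset of controls
        cs_list = list(cs)
        for r in range(1, len(cs_list) + 1):
            for subset in itertools.combinations(cs_list, r):
                cost = sum(abs(pt[t0] - pc[c]) for c in subset)
                rem = tuple(c for c in cs_list if c not in subset)
                best = min(best, cost + rec(rest, rem))
        # t0 is a leaf of a control-centre c, together with other treated
        for c in cs_list:
            others = [t for t in rest]
            for r in range(0, len(others) + 1):
                for extra in itertools.combinations(others, r):
                    group = (t0, *extra)
                    cost = sum(abs(pt[t] - pc[c]) for t in group)
                    rem_t = tuple(t for t in rest if t not in extra)
                    rem_c = tuple(x for x in cs_list if x != c)
                    best = min(best, cost + rec(rem_t, rem_c))
        return best

    return rec(tuple(range(nt)), tuple(range(nc)))


class TestFullMatching:
    def test_one_pair(self):
        data, ps = study_from_ps([0.4], [0.6])
        m = match_full(data, ps)
        assert np.allclose(m.weights, [1.0, 1.0])
        assert len(m.sets) == 1

    def test_hand_case_two_sets(self):
        data, ps = study_from_ps([0.2, 0.8], [0.19, 0.21, 0.81])
        m = match_full(data, ps)
        sets = {tuple(sorted(ts)): tuple(sorted(cs)) for ts, cs in m.sets}
        assert sets == {(0,): (2, 3), (1,): (4,)}
        assert m.extra["total_distance"] == pytest.approx(0.02 + 0.01)

    def test_every_unit_in_exactly_one_set(self, good_spec):
        data = generate_dataset(good_spec, 200, seed=8)
        ps = fit_propensity_parametric(data)
        m = match_full(data, ps)
        seen = [i for ts, cs in m.sets for i in (*ts, *cs)]
        assert sorted(seen) == list(range(200))
        for ts, cs in m.sets:
            assert ts and cs

    def test_identical_ps_any_partition_conserves_weight(self):
        data, ps = study_from_ps([0.5, 0.5], [0.5, 0.5, 0.5])
        m = match_full(data, ps)
        assert m.weights[data.treatment == 0].sum() == pytest.approx(2.0)
        assert m.extra["total_distance"] == pytest.approx(0.0)

    def test_matches_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(40):
            nt = int(rng.integers(1, 5))
            nc = int(rng.integers(1, 5))
            pt = rng.uniform(size=nt)
            pc = rng.uniform(size=nc)
            data, ps = study_from_ps(pt, pc, seed=int(rng.integers(2**31)))
            got = match_full(data, ps).extra["total_distance"]
            assert got == pytest.approx(_star_partition_oracle(pt, pc), abs=1e-12)


class TestIPTW:
    @pytest.mark.parametrize("p, expected", [(0.5, 1.0), (0.8, 4.0)])
    def test_control_odds_weight(self, p, expected):
        data, _ = study_from_ps([0.5], [p])
        m = weights_iptw_att(np.array([0.5, p]), data.treatment)
        assert m.weights[1] == pytest.approx(expected)

    def test_treated_weight_always_one(self):
        data, ps = study_from_ps([0.1, 0.6, 0.93], [0.5])
        m = weights_iptw_att(ps, data.treatment)
        assert np.array_equal(m.weights[data.treatment == 1], np.ones(3))

    def test_degenerate_ps_rejected(self):
        data, _ = study_from_ps([0.5], [0.5])
        with pytest.raises(ValueError):
            weights_iptw_att(np.array([1.0, 0.5]), data.treatment)


class TestGenMahalanobis:
    def test_identity_reduces_to_classical(self):
        rng = np.random.default_rng(23)
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        x, y = rng.normal(size=2), rng.normal(size=2)
        d = gen_mahalanobis(x, y, S, np.eye(2))
        classical = np.sqrt((x - y) @ np.linalg.inv(S) @ (x - y))
        assert d == pytest.approx(classical, abs=1e-12)

    def test_zero_distance_for_equal_points(self):
        S = np.eye(3)
        x = np.array([1.0, 2.0, 3.0])
        assert gen_mahalanobis(x, x, S, np.diag([1, 5, 9])) == 0.0

    def test_hand_computed_diagonal_case(self):
        S = np.diag([4.0, 1.0])
        W = np.diag([1.0, 9.0])
        d = gen_mahalanobis([2.0, 1.0], [0.0, 0.0], S, W)
        assert d == pytest.approx(np.sqrt(10.0), abs=1e-12)

    def test_singular_scale_raises(self):
        S = np.ones((2, 2))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            gen_mahalanobis([1.0, 0.0], [0.0, 0.0], S, np.eye(2))


class TestGenetic:
    CFG = GAConfig(pop_size=10, generations=4, seed=5)

    def test_paired_clones_reach_zero_asmd(self):
        rng = np.random.default_rng(24)
        Xt = rng.normal(size=(15, 2))
        data = StudyData(
            covariates=pd.DataFrame(np.vstack([Xt, Xt]), columns=["U", "V"]),
            treatment=np.r_[np.ones(15, int), np.zeros(15, int)],
            outcome=rng.normal(size=30),
        )
        m = match_genetic(data, self.CFG)
        assert max(m.extra["fitness"]) == pytest.approx(0.0, abs=1e-12)

    def test_seeded_determinism(self, good_spec):
        data = generate_dataset(good_spec, 120, seed=9)
        m1 = match_genetic(data, self.CFG)
        m2 = match_genetic(data, self.CFG)
        assert np.array_equal(m1.weights, m2.weights)
        assert np.array_equal(m1.extra["W"], m2.extra["W"])

    def test_single_covariate_equals_plain_nn(self):
        rng = np.random.default_rng(25)
        x = rng.normal(size=40)
        data = StudyData(
            covariates=pd.DataFrame({"X": x}),
            treatment=np.r_[np.ones(15, int), np.zeros(25, int)],
            outcome=rng.normal(size=40),
        )
        m = match_genetic(data, self.CFG)
        # direct NN on the covariate (weight-free for one covariate)
        xt, xc = x[:15], x[15:]
        picks = np.array([np.argmin(np.abs(xc - v)) for v in xt])
        counts = np.bincount(picks, minlength=25).astype(float)
        expect = np.r_[np.ones(15), counts / counts.sum() * 15]
        assert np.allclose(m.weights, expect)


class TestInvariantsAcrossMethods:
    def test_weight_conservation(self, good_spec):
        data = generate_dataset(good_spec, 300, seed=10)
        ps = fit_propensity_parametric(data)
        for fn in (match_greedy_nn, match_optimal, match_full):
            m = fn(data, ps)
            assert m.weights[data.treatment == 0].sum() == pytest.approx(
                m.weights[data.treatment == 1].sum(), abs=1e-9
            )
        m = match_subclassification(data, ps, 10)
        assert m.weights[data.treatment == 0].sum() == pytest.approx(
            m.weights[data.treatment == 1].sum(), abs=1e-9
        )

    def test_permutation_equivariance(self, good_spec):
        data = generate_dataset(good_spec, 80, seed=12)
        ps = fit_propensity_parametric(data).fitted_ps
        rng = np.random.default_rng(0)
        perm = rng.permutation(80)
        pdata = StudyData(
            covariates=data.covariates.iloc[perm].reset_index(drop=True),
            treatment=data.treatment[perm],
            outcome=data.outcome[perm],
        )
        # optimal: with distinct propensities the assignment is unique
        w = match_optimal(data, ps).weights
        wp = match_optimal(pdata, ps[perm]).weights
        assert np.allclose(wp, w[perm], atol=1e-9)
        # full matching may have tied optima; the objective value must agree
        f = match_full(data, ps)
        fp = match_full(pdata, ps[perm])
        assert fp.extra["total_distance"] == pytest.approx(
            f.extra["total_distance"], abs=1e-9
        )


@pytest.mark.parametrize(
    "weights, expected",
    [([3, 3, 3, 3], 4.0), ([1, 0, 0], 1.0), ([1, 1, 2], 16 / 6)],
)
def test_effective_sample_size(weights, expected):
    assert effective_sample_size(weights) == pytest.approx(expected)
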