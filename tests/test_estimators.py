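import numpy as np
import pytest

from rdsvar import (
    BlockSpec,
    InsufficientChainsError,
    VarianceEstimate,
    chain_from_matrix,
    collapsed_chain,
    coverage_hit,
    estimate_transitions,
    exact_rw_variance,
    rds2_mean,
    sbe_variance,
    step_covariance,
    vhe_variance,
)
from conftest import simulate_category_forest
from rdsvar.sampler import Record, RecruitmentForest


def make_forest(ys, degrees=None, recruiters=None):
    degrees = degrees or [2] * len(ys)
    if recruiters is None:
        recruiters = [None] + list(range(len(ys) - 1))
    waves, records = [], []
    for i, (y, d, rec) in enumerate(zip(ys, degrees, recruiters)):
        wave = 0 if rec is None else waves[rec] + 1
        waves.append(wave)
        records.append(Record(str(i), rec, wave, y, d))
    return RecruitmentForest(records=tuple(records))


class TestRDS2Mean:
    def test_equal_degrees_is_arithmetic_mean(self):
        f = make_forest([1, 0, 1, 1])
        assert rds2_mean(f) == pytest.approx(0.75)

    def test_inverse_degree_weighting(self):
        f = make_forest([1, 0, 1], degrees=[1, 2, 2])
        assert rds2_mean(f) == pytest.approx(0.75)

    def test_constant_attribute(self):
        f = make_forest([1, 1, 1], degrees=[1, 5, 9])
        assert rds2_mean(f) == 1.0

    def test_zero_degree_rejected(self):
        with pytest.raises(ValueError, match="degrees"):
            rds2_mean(make_forest([1, 0], degrees=[0, 2]))


class TestEstimateTransitions:
    def test_row_normalized_tallies(self):
        # referral value pairs: 0->0 x2, 0->1, 1->1 x2, 1->0
        f = make_forest([0, 0, 0, 1, 1, 1, 0])
        est = estimate_transitions(f, order=1)
        assert np.allclose(est.matrix, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]])
        assert est.counts.sum() == 6

    def test_single_category_flagged_degenerate(self):
        est = estimate_transitions(make_forest([0, 0, 0, 0]), order=1)
        assert est.degenerate

    def test_order2_structural_zeros(self):
        rng = np.random.default_rng(2)
        f = simulate_category_forest(1 / 4, 400, rng)
        est = estimate_transitions(f, order=2)
        for i, si in enumerate(est.states):
            for j, sj in enumerate(est.states):
                if sj[:-1] != si[1:]:
                    assert est.matrix[i, j] == 0.0
        assert est.matrix.shape == (4, 4)

    def test_order2_consistent_with_order1_on_fom_data(self):
        rng = np.random.default_rng(3)
        f = simulate_category_forest(1 / 4, 5000, rng)
        e1 = estimate_transitions(f, order=1)
        e2 = estimate_transitions(f, order=2)
        # Pr(y | prev, prevprev) should match Pr(y | prev) within sampling error
        for i, s in enumerate(e2.states):
            prev = int(s[-1])
            n_row = e2.counts[i].sum()
            if n_row < 50:
                continue
            p2 = e2.matrix[i, [k for k, t in enumerate(e2.states) if t[-1] == "1"]].sum()
            p1 = e1.matrix[prev, 1]
            assert abs(p2 - p1) < 4 * np.sqrt(p1 * (1 - p1) / n_row)

    def test_insufficient_chains_error(self):
        f = make_forest([1, 0], recruiters=[None, None])
        with pytest.raises(InsufficientChainsError):
            estimate_transitions(f, order=1)

    def test_covariances_match_spectral_oracle(self):
        # a TransitionEstimate carrying the exact example-1 collapse as its
        # matrix must reproduce the chain's eigen-sum covariances
        from rdsvar import TransitionEstimate

        chain = collapsed_chain(BlockSpec(e=10, f=10, h=10))
        forced = TransitionEstimate(
            order=1, states=("0", "1"), matrix=chain.P,
            counts=chain.P * 12, weights=chain.pi,
            defined=np.array([True, True]), lambdas=chain.lambdas,
        )
        got = forced.covariances(10)
        want = [step_covariance(chain, t) for t in range(1, 11)]
        assert np.allclose(got, want, atol=1e-12)


class TestVHEVariance:
    def test_constant_attribute_zero_variance(self):
        est = vhe_variance(make_forest([1] * 10))
        assert est.variance == 0.0
        assert "degenerate_single_category" in est.flags

    def test_tree_equals_sequence_on_pure_chain(self):
        rng = np.random.default_rng(4)
        f = simulate_category_forest(1 / 6, 100, rng)
        a = vhe_variance(f, distance_mode="sequence")
        b = vhe_variance(f, distance_mode="tree")
        assert a.variance == pytest.approx(b.variance, abs=1e-12)

    def test_fom_regime_approximately_unbiased(self):
        # mean VHE over chains simulated from the known 2-state collapse is
        # close to the exact chain variance; the plug-in stationary variance
        # leaves a small O(DE/S) downward bias, hence the relative band
        chain = collapsed_chain(BlockSpec(e=10, f=10, h=10))
        exact = exact_rw_variance(chain, 100).variance
        rng = np.random.default_rng(5)
        ests = [vhe_variance(simulate_category_forest(1 / 6, 100, rng)).variance
                for _ in range(400)]
        assert np.mean(ests) == pytest.approx(exact, rel=0.12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        f = simulate_category_forest(1 / 5, 150, rng,
                                     branch_probs=(1 / 3, 1 / 6, 1 / 6, 1 / 3))
        flipped = RecruitmentForest(records=tuple(
            Record(r.node, r.recruiter, r.wave, 1 - r.y, r.degree)
            for r in f.records))
        for mode, order in (("sequence", 1), ("tree", 1), ("tree", 2)):
            a = vhe_variance(f, distance_mode=mode, order=order)
            b = vhe_variance(flipped, distance_mode=mode, order=order)
            assert a.variance == pytest.approx(b.variance, abs=1e-12)
            assert a.mean == pytest.approx(1 - b.mean, abs=1e-12)

    def test_order2_recovers_true_second_order_chain(self):
        # y-process with genuine second-order memory: transition depends on
        # the previous pair; exact variance from the lifted 4-state chain
        # moderate memory keeps the design effect (hence the O(DE/S) plug-in
        # bias of any sample-based estimator) small relative to the band
        pr1 = {"00": 0.25, "01": 0.5, "10": 0.5, "11": 0.75}
        states = ("00", "01", "10", "11")
        P = np.zeros((4, 4))
        for i, s in enumerate(states):
            for j, t in enumerate(states):
                if t[0] == s[1]:
                    P[i, j] = pr1[s] if t[1] == "1" else 1 - pr1[s]
        lifted = chain_from_matrix(P, np.array([float(s[-1]) for s in states]))
        exact = exact_rw_variance(lifted, 120).variance

        rng = np.random.default_rng(7)
        ests = []
        for _ in range(300):
            ys = [0, int(rng.random() < 0.5)]
            for _ in range(168):  # 50-step burn-in approximates a stationary start
                key = f"{ys[-2]}{ys[-1]}"
                ys.append(int(rng.random() < pr1[key]))
            f = make_forest(ys[50:])
            ests.append(vhe_variance(f, distance_mode="tree", order=2).variance)
        assert np.mean(ests) == pytest.approx(exact, rel=0.15)

    def test_order2_requires_triples(self):
        f = make_forest([1, 0, 1], recruiters=[None, 0, None])
        with pytest.raises(InsufficientChainsError):
            vhe_variance(f, order=2)


class TestSBEVariance:
    def test_constant_sample_zero_variance(self):
        est = sbe_variance(make_forest([1] * 20), b=200, seed=1)
        assert est.variance == 0.0

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(8)
        f = simulate_category_forest(1 / 6, 80, rng)
        a = sbe_variance(f, b=300, seed=42)
        b = sbe_variance(f, b=300, seed=42)
        assert a.variance == b.variance

    def test_bootstrap_convergence(self):
        rng = np.random.default_rng(9)
        f = simulate_category_forest(1 / 6, 100, rng)
        a = sbe_variance(f, b=5000, seed=1)
        b = sbe_variance(f, b=5000, seed=2)
        assert abs(a.variance - b.variance) / a.variance < 0.05

    def test_identity_matrix_seed_draw_variance(self):
        # perfect observed homophily: chains never switch category, so the
        # replicate mean is the seed category and the bootstrap variance
        # approaches p1*(1-p1) (all y=c chains give mean exactly c)
        ys = [0] * 10 + [1] * 10
        recruiters = [None] + list(range(9)) + [None] + list(range(10, 19))
        f = make_forest(ys, recruiters=recruiters)
        est = sbe_variance(f, b=4000, seed=3)
        p1 = 0.5
        se = np.sqrt(2.0 / 4000) * p1 * (1 - p1)  # variance-of-variance scale
        assert est.variance == pytest.approx(p1 * (1 - p1), abs=4 * se + 0.01)


class TestCoverageHit:
    def test_exact_mean_always_covered(self):
        est = VarianceEstimate(method="VHE", mean=0.4, variance=0.0,
                               design_effect=1.0)
        assert coverage_hit(est, 0.4)

    def test_zero_variance_missed(self):
        est = VarianceEstimate(method="VHE", mean=0.4, variance=0.0,
                               design_effect=1.0)
        assert not coverage_hit(est, 0.5)

    def test_boundary_arithmetic(self):
        est = VarianceEstimate(method="VHE", mean=0.5, variance=0.0025,
                               design_effect=1.0)
        assert coverage_hit(est, 0.598)
        assert not coverage_hit(est, 0.599)
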