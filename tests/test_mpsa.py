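"""Latin hypercube sampling, classification, sensitivity indices, full MPSA."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from makit import (
    MPSAConfig,
    MPSAError,
    OdeMseBackend,
    PmcRewardBackend,
    Reaction,
    ReactionNetwork,
    RewardSpec,
    Species,
    TargetPredicate,
    classify,
    ecdf,
    enumerate_states,
    expected_reward_to_target,
    ks_statistic,
    lhs_sample,
    pmcc_index,
    run_mpsa,
    sample_error_ode,
    sample_error_pmc,
    set_parameters,
    simulate,
    trajectory_mse,
)


def ks_brute_force(a, b):
    """Double-loop oracle for the two-sample KS statistic."""
    pooled = sorted(set(a) | set(b))
    best = 0.0
    for t in pooled:
        fa = sum(1 for v in a if v <= t) / len(a)
        fb = sum(1 for v in b if v <= t) / len(b)
        best = max(best, abs(fa - fb))
    return best


class TestLhsSample:
    def test_one_sample_per_stratum(self):
        x = lhs_sample(4, [(0.0, 1.0)], seed=0)[:, 0]
        strata = np.floor(x * 4).astype(int)
        assert sorted(strata) == [0, 1, 2, 3]

    @given(st.integers(2, 40), st.integers(0, 2**31 - 1))
    def test_stratification_exact_for_any_n_and_seed(self, n, seed):
        x = lhs_sample(n, [(2.0, 6.0), (0.1, 0.2)], seed=seed)
        for j, (lo, hi) in enumerate([(2.0, 6.0), (0.1, 0.2)]):
            strata = np.floor((x[:, j] - lo) / (hi - lo) * n).astype(int)
            strata = np.clip(strata, 0, n - 1)  # guard hi endpoint round-off
            assert sorted(strata) == list(range(n))

    def test_seed_reproducibility(self):
        a = lhs_sample(100, [(0, 1), (5, 9)], seed=7)
        b = lhs_sample(100, [(0, 1), (5, 9)], seed=7)
        assert np.array_equal(a, b)

    def test_close_to_uniform_at_large_n(self):
        x = np.sort(lhs_sample(1000, [(0.0, 1.0)], seed=1)[:, 0])
        # one-sample KS distance of the ECDF to the uniform CDF
        n = len(x)
        d = max(
            max(abs((i + 1) / n - x[i]), abs(i / n - x[i])) for i in range(n)
        )
        assert d < 0.05

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            lhs_sample(10, [(1.0, 1.0)], seed=0)


class TestClassify:
    def test_half_below_median(self):
        assert classify(np.array([1.0, 2, 3, 4])).tolist() == [True, True, False, False]

    def test_tie_at_median(self):
        # median of [5,5,1,9] is 5; only 1 is strictly below
        assert classify(np.array([5.0, 5, 1, 9])).tolist() == [False, False, True, False]

    def test_even_n_distinct_splits_exactly_in_half(self):
        rng = np.random.default_rng(0)
        errors = rng.permutation(400).astype(float)
        assert classify(errors).sum() == 200

    def test_identical_errors_degenerate(self):
        with pytest.raises(MPSAError):
            classify(np.full(10, 3.14))


class TestEcdf:
    def test_single_point(self):
        f = ecdf([1.0])
        assert f(0.5) == 0.0 and f(1.0) == 1.0

    def test_two_points(self):
        f = ecdf([1.0, 2.0])
        assert f(1.0) == 0.5 and f(2.0) == 1.0

    def test_normalization(self):
        f = ecdf([3.0, 1.0, 2.0])
        assert f(0.0) == 0.0 and f(10.0) == 1.0


class TestKsStatistic:
    def test_identical_samples_zero(self):
        assert ks_statistic([1.0, 2, 3], [1.0, 2, 3]) == 0.0

    def test_disjoint_supports_one(self):
        assert ks_statistic([1.0, 2], [5.0, 6]) == 1.0

    def test_hand_evaluated_overlap(self):
        assert ks_statistic([1.0, 2, 3], [2.0, 3, 4]) == pytest.approx(1 / 3)

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=15),
        st.lists(st.floats(-5, 5), min_size=1, max_size=15),
    )
    def test_matches_brute_force_double_loop(self, a, b):
        assert ks_statistic(a, b) == pytest.approx(ks_brute_force(a, b), abs=1e-12)


class TestPmccIndex:
    def test_identical_samples_zero(self):
        assert pmcc_index([1.0, 2, 3], [1.0, 2, 3]) == pytest.approx(0.0)

    def test_symmetry(self):
        a, b = [1.0, 2, 5, 7], [0.5, 3, 4, 9]
        assert pmcc_index(a, b) == pytest.approx(pmcc_index(b, a))

    def test_matches_direct_pearson_on_pooled_grid(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 30), rng.normal(3, 1, 25)
        grid = np.unique(np.concatenate([a, b]))
        fa = np.array([np.mean(a <= t) for t in grid])
        fb = np.array([np.mean(b <= t) for t in grid])
        r = np.corrcoef(fa, fb)[0, 1]
        assert pmcc_index(a, b) == pytest.approx(1 - r, abs=1e-12)

    def test_shifted_sample_less_correlated_than_identical(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 1, 40)
        assert pmcc_index(a, a + 50.0) > pmcc_index(a, a)


class TestSampleErrors:
    def test_ode_error_zero_at_nominal(self, enzymatic):
        be = OdeMseBackend()
        ref = be.reference(enzymatic)
        err = sample_error_ode(enzymatic, {"r1": 0.184, "r3": 0.211}, ref)
        assert err == pytest.approx(0.0, abs=1e-10)

    def test_ode_error_matches_composition_oracle(self, enzymatic):
        ref = simulate(enzymatic)
        sample = {"r3": 4 * 0.211}
        err = sample_error_ode(enzymatic, sample, ref)
        direct = trajectory_mse(
            simulate(set_parameters(enzymatic, sample)), ref, "P"
        )
        assert err == pytest.approx(direct, rel=1e-12)

    def test_pmc_error_zero_at_nominal(self, enzymatic):
        be = PmcRewardBackend()
        ref, reward, target = be.reference(enzymatic)
        assert sample_error_pmc(
            enzymatic, {"r1": 0.184}, ref, reward, target
        ) == pytest.approx(0.0, abs=1e-10)

    def test_pmc_error_uses_exact_no_dissociation_value(self, enzymatic):
        net = enzymatic.with_initial("E", 1)
        reward, target = RewardSpec("r1"), TargetPredicate("P", ">=", 6)
        ref = expected_reward_to_target(enumerate_states(net), reward, target)
        err = sample_error_pmc(net, {"r2": 0.0}, ref, reward, target)
        assert err == pytest.approx(abs(6.0 - ref), abs=1e-9)


class TestRunMpsa:
    def test_reproducible_for_fixed_seed(self, enzymatic):
        cfg = MPSAConfig(parameters=("r1", "r3"), n_samples=40, seed=5)
        a = run_mpsa(enzymatic, cfg)
        b = run_mpsa(enzymatic, cfg)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.errors, b.errors)
        assert a.indices == b.indices and a.rankings == b.rankings

    def test_acceptable_partition(self, enzymatic):
        cfg = MPSAConfig(parameters=("r1", "r3"), n_samples=40, seed=5)
        res = run_mpsa(enzymatic, cfg)
        assert len(res.failed) == 0
        assert res.acceptable.sum() == 20  # even n, distinct errors

    def test_ode_backend_ranks_conversion_above_association(self, enzymatic):
        cfg = MPSAConfig(parameters=("r1", "r3"), n_samples=400, seed=0,
                         backend=OdeMseBackend(species="P"))
        res = run_mpsa(enzymatic, cfg)
        assert res.indices["r3"]["ks"] > res.indices["r1"]["ks"]
        assert res.indices["r3"]["pmcc"] > res.indices["r1"]["pmcc"]
        assert res.rankings["ks"][0] == "r3" and res.rankings["pmcc"][0] == "r3"

    def test_pmc_backend_ranks_association_above_conversion(self, enzymatic):
        cfg = MPSAConfig(parameters=("r1", "r3"), n_samples=400, seed=0,
                         backend=PmcRewardBackend())
        res = run_mpsa(enzymatic, cfg)
        assert res.indices["r1"]["ks"] > res.indices["r3"]["ks"]
        assert res.indices["r1"]["pmcc"] > res.indices["r3"]["pmcc"]
        assert res.rankings["ks"][0] == "r1" and res.rankings["pmcc"][0] == "r1"

    def test_uninfluential_parameter_has_small_ks_index(self):
        """A rate of a never-enabled reaction should show index ~ 0.

        At n=400 the KS index of a pure-noise parameter stays below the 5%
        two-sample critical value 1.36*sqrt(4/n).
        """
        net = ReactionNetwork(
            [
                Species("S", 12), Species("E", 10), Species("ES", 0),
                Species("P", 0), Species("X", 0), Species("Y", 0),
            ],
            [
                Reaction("r1", {"E": 1, "S": 1}, {"ES": 1}, 0.184),
                Reaction("r2", {"ES": 1}, {"E": 1, "S": 1}, 0.016),
                Reaction("r3", {"ES": 1}, {"E": 1, "P": 1}, 0.211),
                Reaction("dead", {"X": 1}, {"Y": 1}, 1.0),  # X starts at 0
            ],
        )
        cfg = MPSAConfig(parameters=("r3", "dead"), n_samples=400, seed=1)
        res = run_mpsa(net, cfg)
        assert res.indices["dead"]["ks"] < 1.36 * np.sqrt(4 / 400)
        assert res.indices["dead"]["ks"] < res.indices["r3"]["ks"]

    def test_unknown_parameter_rejected(self, enzymatic):
        with pytest.raises(KeyError):
            run_mpsa(enzymatic, MPSAConfig(parameters=("k9",), n_samples=10, seed=0))

    def test_report_dict_is_json_ready(self, enzymatic):
        import json

        cfg = MPSAConfig(parameters=("r1", "r3"), n_samples=20, seed=2)
        res = run_mpsa(enzymatic, cfg)
        text = json.dumps(res.to_dict(), sort_keys=True)
        assert '"seed": 2' in text
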