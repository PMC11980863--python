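"""Probabilistic core against independent oracles: matrix exponentials,
brute-force state enumeration, numeric integrators and closed forms."""

import numpy as np
import pytest
from scipy import stats

from tipdating.clock_model import (
    CalibrationPrior,
    ClockModel,
    DemographicModel,
    ParameterPriors,
    SubstitutionParams,
    coalescent_log_density,
    gmrf_log_prior,
    hky_transition_matrix,
    log_posterior,
    log_prior,
    partition_log_likelihood,
    site_rate_mixture,
)
from tipdating.synthetic_data import simulate_genealogy
from tipdating.trees import parse_newick

from oracles import (
    brute_force_log_likelihood,
    coalescent_numeric_log_density,
    gamma_category_rates_numeric,
    hky_expm,
    random_sequences,
    random_time_tree,
)


@pytest.fixture
def params():
    return SubstitutionParams(kappa=2.0, freqs=[0.3, 0.2, 0.2, 0.3],
                              gamma_shape=0.5, p_inv=0.2)


class TestHKYTransitionMatrix:
    def test_matches_matrix_exponential(self, rng):
        for _ in range(20):
            kappa = float(rng.uniform(0.5, 30))
            freqs = rng.dirichlet([5, 5, 5, 5])
            d = float(rng.uniform(0, 2))
            p = SubstitutionParams(kappa=kappa, freqs=freqs / freqs.sum())
            P = hky_transition_matrix(p, d)
            assert np.abs(P - hky_expm(kappa, p.freqs, d)).max() < 1e-10
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-12
            assert (P >= 0).all()

    def test_zero_distance_is_identity(self, params):
        assert np.abs(hky_transition_matrix(params, 0.0) - np.eye(4)).max() < 1e-12

    def test_long_distance_reaches_stationarity(self, params):
        P = hky_transition_matrix(params, 50.0)
        assert np.abs(P - params.freqs[None, :]).max() < 1e-8

    def test_detailed_balance(self, params):
        P = hky_transition_matrix(params, 0.37)
        flux = params.freqs[:, None] * P
        assert np.abs(flux - flux.T).max() < 1e-10

    def test_negative_distance_rejected(self, params):
        with pytest.raises(ValueError):
            hky_transition_matrix(params, -0.1)


class TestSiteRateMixture:
    def test_degenerate_gamma_collapses_to_rate_one(self):
        cats = site_rate_mixture(1e9, 4, 0.0)
        assert max(abs(r - 1) for r, _ in cats) < 1e-4

    def test_invariant_only_mixture(self):
        assert site_rate_mixture(None, 4, 0.5) == [(0.0, 0.5), (2.0, 0.5)]

    @pytest.mark.parametrize("alpha,n", [(0.5, 4), (0.2, 4), (2.0, 8)])
    def test_rates_match_numeric_integration(self, alpha, n):
        cats = site_rate_mixture(alpha, n, 0.0)
        rates = np.array([r for r, _ in cats])
        expected = gamma_category_rates_numeric(alpha, n)
        np.testing.assert_allclose(rates, expected, atol=1e-8)
        weights = np.array([w for _, w in cats])
        assert abs(float(weights @ rates) - 1.0) < 1e-12

    def test_mixture_mean_is_one_with_invariants(self):
        cats = site_rate_mixture(0.3, 4, 0.4)
        assert sum(r * w for r, w in cats) == pytest.approx(1.0, abs=1e-12)

    def test_pinv_one_rejected(self):
        with pytest.raises(ValueError):
            site_rate_mixture(0.5, 4, 1.0)


class TestPartitionLogLikelihood:
    def test_fully_ambiguous_site_has_likelihood_one(self, params):
        tree = parse_newick("(a:1,b:1);")
        ll = partition_log_likelihood(tree, [("a", "N"), ("b", "N")], params,
                                      ClockModel(1e-2))
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_identical_bases_at_negligible_distance(self, params):
        # branch durations of 1 year at the minimum clock rate: the path
        # length in substitutions is ~2e-12, numerically zero
        tree = parse_newick("(a:1,b:1);")
        ll = partition_log_likelihood(tree, [("a", "A"), ("b", "A")], params,
                                      ClockModel(1e-12))
        assert ll == pytest.approx(np.log(params.freqs[0]), abs=1e-10)

    def test_matches_brute_force_enumeration(self, rng):
        """Pruning equals summing over all internal state assignments
        (randomized trees up to 5 tips, mixed alphabets, 100 cases)."""
        clock = ClockModel(0.4)
        for case in range(100):
            n = int(rng.integers(2, 6))
            tree = random_time_tree(rng, n)
            params = SubstitutionParams(
                kappa=float(rng.uniform(0.5, 20)),
                freqs=rng.dirichlet([8, 8, 8, 8]),
                gamma_shape=float(rng.uniform(0.2, 3)) if rng.random() < 0.7 else None,
                p_inv=float(rng.uniform(0, 0.5)),
                relative_rate=float(rng.uniform(0.5, 2)),
            )
            length = int(rng.integers(1, 51))
            records = random_sequences(rng, tree.labels, length)
            ll = partition_log_likelihood(tree, records, params, clock)
            oracle = brute_force_log_likelihood(tree, records, params, clock)
            assert ll == pytest.approx(oracle, abs=1e-10), f"case {case}"

    def test_site_order_invariance(self, rng, params):
        tree = random_time_tree(rng, 5)
        records = random_sequences(rng, tree.labels, 40)
        perm = rng.permutation(40)
        shuffled = [(rid, "".join(seq[i] for i in perm)) for rid, seq in records]
        clock = ClockModel(0.3)
        assert partition_log_likelihood(tree, records, params, clock) == pytest.approx(
            partition_log_likelihood(tree, shuffled, params, clock), abs=1e-9)

    def test_jukes_cantor_closed_form_two_tips(self):
        """kappa=1, equal frequencies reduces to Jukes-Cantor."""
        params = SubstitutionParams(kappa=1.0, freqs=[0.25] * 4)
        clock = ClockModel(1.0)
        tree = parse_newick("(a:0.05,b:0.05);")
        d = 0.1  # total path
        p_same = 0.25 + 0.75 * np.exp(-4 * d / 3)
        ll_same = partition_log_likelihood(tree, [("a", "A"), ("b", "A")], params, clock)
        ll_diff = partition_log_likelihood(tree, [("a", "A"), ("b", "C")], params, clock)
        assert ll_same == pytest.approx(np.log(0.25 * p_same), abs=1e-10)
        assert ll_diff == pytest.approx(np.log(0.25 * (1 - p_same) / 3), abs=1e-10)

    def test_label_mismatch_rejected(self, params):
        tree = parse_newick("(a:1,b:1);")
        with pytest.raises(ValueError, match="missing"):
            partition_log_likelihood(tree, [("a", "A")], params, ClockModel(0.1))


class TestCoalescentLogDensity:
    def test_two_tip_closed_form(self):
        tree = parse_newick("(a:7,b:7);")
        ne = 3.0
        expected = -np.log(ne) - 7.0 / ne
        got = coalescent_log_density(tree, DemographicModel(mode="constant", Ne=ne))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_grid_with_equal_sizes_reduces_to_constant(self, rng):
        tree = random_time_tree(rng, 6, max_tip_age=2.0)
        const = DemographicModel(mode="constant", Ne=1.7)
        grid = DemographicModel(mode="grid", boundaries=[1.0, 2.0, 5.0],
                                sizes=[1.7] * 4, gmrf_precision=1.0)
        assert coalescent_log_density(tree, grid) == pytest.approx(
            coalescent_log_density(tree, const), abs=1e-10)

    def test_heterochronous_grid_matches_numeric_integrator(self, rng):
        for _ in range(10):
            tree = random_time_tree(rng, 5, max_tip_age=3.0)
            k = int(rng.integers(1, 4))
            grid = DemographicModel(
                mode="grid",
                boundaries=np.sort(rng.uniform(0.5, 6.0, size=k)),
                sizes=rng.uniform(0.5, 5.0, size=k + 1),
                gmrf_precision=1.0,
            )
            assert coalescent_log_density(tree, grid) == pytest.approx(
                coalescent_numeric_log_density(tree, grid), abs=1e-10)

    def test_constant_heterochronous_matches_numeric_integrator(self, rng):
        demog = DemographicModel(mode="constant", Ne=2.5)
        for _ in range(10):
            tree = random_time_tree(rng, 5, max_tip_age=3.0)
            assert coalescent_log_density(tree, demog) == pytest.approx(
                coalescent_numeric_log_density(tree, demog), abs=1e-10)


class TestGmrfLogPrior:
    def test_two_epoch_closed_form(self):
        demog = DemographicModel(mode="grid", boundaries=[1.0],
                                 sizes=[1.0, np.e], gmrf_precision=1.0)
        priors = ParameterPriors()
        expected_inc = -0.5 - 0.5 * np.log(2 * np.pi)
        expected_tau = stats.gamma.logpdf(1.0, a=priors.gmrf_tau_shape,
                                          scale=1.0 / priors.gmrf_tau_rate)
        assert gmrf_log_prior(demog, priors) == pytest.approx(
            expected_inc + expected_tau, abs=1e-12)

    def test_equal_sizes_maximize_random_walk_term(self, rng):
        flat = DemographicModel(mode="grid", boundaries=[1.0, 2.0],
                                sizes=[2.0, 2.0, 2.0], gmrf_precision=3.0)
        best = gmrf_log_prior(flat)
        for _ in range(10):
            sizes = 2.0 * np.exp(rng.normal(0, 0.5, size=3))
            other = DemographicModel(mode="grid", boundaries=[1.0, 2.0],
                                     sizes=sizes, gmrf_precision=3.0)
            assert gmrf_log_prior(other) <= best + 1e-12

    def test_matches_product_of_normal_increments(self, rng):
        for _ in range(10):
            k = int(rng.integers(2, 6))
            tau = float(rng.uniform(0.1, 5))
            demog = DemographicModel(mode="grid",
                                     boundaries=np.arange(1, k + 1, dtype=float),
                                     sizes=rng.uniform(0.5, 5, size=k + 1),
                                     gmrf_precision=tau)
            priors = ParameterPriors()
            oracle = sum(
                stats.norm.logpdf(np.log(demog.sizes[i + 1]) - np.log(demog.sizes[i]),
                                  scale=tau ** -0.5)
                for i in range(k)
            ) + stats.gamma.logpdf(tau, a=priors.gmrf_tau_shape,
                                   scale=1 / priors.gmrf_tau_rate)
            assert gmrf_log_prior(demog, priors) == pytest.approx(oracle, abs=1e-12)

    def test_constant_mode_rejected(self):
        with pytest.raises(ValueError):
            gmrf_log_prior(DemographicModel(mode="constant", Ne=1.0))


class TestJointPrior:
    def make_state(self, rng):
        demog = DemographicModel(mode="constant", Ne=5e5)
        tree = simulate_genealogy([0.0, 10_000.0, 1_000_500.0], demog, rng,
                                  labels=["c1", "c2", "u1"])
        params = [SubstitutionParams(kappa=8.0, freqs=[0.25] * 4,
                                     gamma_shape=0.4, p_inv=0.1)]
        calib = CalibrationPrior(
            root_median=5.3e6, root_sigma=0.05,
            tip_priors={"c1": ("fixed", 0.0), "c2": ("fixed", 10_000.0),
                        "u1": ("uniform", 1_000.0, 2_000_000.0)},
        )
        return tree, params, ClockModel(3e-8), demog, calib

    def test_tip_outside_uniform_bounds_is_rejected_state(self, rng):
        tree, params, clock, demog, calib = self.make_state(rng)
        i = tree.labels.index("u1")
        tree.age[i] = 500.0  # below the 1 ka bound
        if tree.age[int(tree.parent[i])] <= 500.0:
            tree.age[int(tree.parent[i])] = 1e6
        assert log_prior(tree, params, clock, demog, calib) == -np.inf

    def test_root_at_lognormal_median(self, rng):
        tree, params, clock, demog, calib = self.make_state(rng)
        tree.age[tree.root] = 5.3e6
        lp_with = log_prior(tree, params, clock, demog, calib)
        calib_off = CalibrationPrior(root_median=None, tip_priors=calib.tip_priors)
        lp_without = log_prior(tree, params, clock, demog, calib_off)
        expected = stats.lognorm.logpdf(5.3e6, s=0.05, scale=5.3e6)
        assert lp_with - lp_without == pytest.approx(expected, rel=1e-12)

    def test_posterior_equals_independent_summation(self, rng):
        tree, params, clock, demog, calib = self.make_state(rng)
        records = random_sequences(rng, tree.labels, 60, alphabet="ACGT")
        partitions = {"all": records}
        by_part = {"all": params[0]}
        lp = log_posterior(tree, partitions, by_part, clock, demog, calib)
        oracle = (log_prior(tree, params, clock, demog, calib)
                  + brute_force_log_likelihood(tree, records, params[0], clock))
        assert lp == pytest.approx(oracle, abs=1e-8)

    def test_clock_rate_outside_bounds_rejected(self, rng):
        tree, params, clock, demog, calib = self.make_state(rng)
        lp = log_prior(tree, params, ClockModel(1.0), demog, calib)
        assert lp == -np.inf
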