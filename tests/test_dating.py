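import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.stats import kstest, norm

from mitophylo.chronogram import Chronogram, build_chronogram, chronogram_from_newick
from mitophylo.dating import (
    ClockModel,
    DatingError,
    MCMCConfig,
    TreePriorSpec,
    _bd_log_g,
    ess,
    hpd_interval,
    make_calibration,
    mcc_tree,
    run_dating_mcmc,
    scale_relative_node_age,
    tree_prior_logdensity,
)


class TestCalibrations:
    def test_normal_from_central95(self):
        cal = make_calibration("normal-from-central95", {"lower": 11, "upper": 12.3})
        assert cal.mean == pytest.approx(11.65)
        assert cal.sd == pytest.approx((12.3 - 11) / (2 * 1.959964), abs=1e-4)
        assert cal.sd == pytest.approx(0.3316, abs=1e-3)

    def test_uniform_density(self):
        cal = make_calibration("uniform", {"lower": 11, "upper": 34})
        assert math.exp(cal.logpdf(20.0)) == pytest.approx(1 / 23)
        assert cal.logpdf(10.0) == -math.inf
        assert cal.logpdf(40.0) == -math.inf

    def test_lognormal_matches_root_find_oracle(self):
        cal = make_calibration("lognormal-from-median-CI",
                               {"median": 2.7, "lower": 1.7, "upper": 3.9})
        assert cal.mean == pytest.approx(math.log(2.7))
        # 1-D oracle: minimize the squared mismatch of the central 95% bounds
        mu = math.log(2.7)

        def loss(sd):
            return ((mu - 1.959964 * sd - math.log(1.7)) ** 2
                    + (mu + 1.959964 * sd - math.log(3.9)) ** 2)

        oracle = minimize_scalar(loss, bounds=(1e-4, 2.0), method="bounded").x
        assert cal.sd == pytest.approx(oracle, abs=1e-5)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(DatingError):
            make_calibration("uniform", {"lower": 5, "upper": 3})
        with pytest.raises(DatingError):
            make_calibration("normal-from-central95", {"lower": 12, "upper": 11})

    def test_densities_integrate_to_one(self):
        for family, params, upper in (
                ("normal-from-central95", {"lower": 0.5, "upper": 3.0}, 10),
                ("uniform", {"lower": 11, "upper": 34}, 40),
                ("lognormal-from-median-CI",
                 {"median": 2.7, "lower": 1.7, "upper": 3.9}, 60)):
            cal = make_calibration(family, params)
            mass, _ = quad(lambda t: math.exp(cal.logpdf(t)), 1e-9, upper,
                           limit=200)
            assert mass == pytest.approx(1.0, abs=1e-6)


class TestTreePriors:
    def test_two_taxon_coalescent_exponential(self):
        spec = TreePriorSpec("coalescent", pop_size=1.0)
        for t in (0.3, 1.0, 2.5):
            assert tree_prior_logdensity([t], spec) == pytest.approx(-t)

    def test_birth_death_zero_death_equals_yule(self):
        t = np.array([0.4, 1.3, 2.2])
        lam = 0.8
        bd = _bd_log_g(t, lam, 0.0)
        yule = np.log(lam) - lam * t
        assert np.allclose(bd, yule)
        # algebraic limit: death -> 0+ converges to the pure-birth density
        near = _bd_log_g(t, lam, 1e-9)
        assert np.allclose(near, yule, atol=1e-6)

    def test_bd_density_integrates_to_one_for_two_taxa(self):
        spec = TreePriorSpec("birth-death", birth_rate=0.9, death_rate=0.4)
        mass, err = quad(lambda t: math.exp(tree_prior_logdensity([t], spec)),
                         0, 400)
        assert abs(mass - 1.0) < 1e-6

    def test_invalid_specs_rejected(self):
        with pytest.raises(DatingError):
            TreePriorSpec("birth-death", birth_rate=0.3, death_rate=0.5)
        with pytest.raises(DatingError):
            TreePriorSpec("coalescent", pop_size=0.0)


class TestESS:
    def test_iid_normal(self, rng):
        x = rng.normal(size=10_000)
        val, flag = ess(x)
        assert not flag
        assert 8_000 <= val <= 12_000

    def test_ar1_closed_form(self, rng):
        rho, n = 0.9, 10_000
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * math.sqrt(1 - rho ** 2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        val, _ = ess(x)
        assert abs(val - expected) / expected < 0.25

    def test_duplicated_trace_halves_ess(self, rng):
        x = rng.normal(size=4000)
        doubled = np.repeat(x, 2)
        v1, _ = ess(x)
        v2, _ = ess(doubled)
        assert abs(v2 - v1) / v1 < 0.25

    def test_constant_trace_flagged(self):
        val, flag = ess(np.full(100, 3.3))
        assert flag and val == 100.0


class TestHPD:
    def test_uniform_order_statistics(self):
        lo, hi = hpd_interval(np.arange(1, 101), 0.95)
        assert hi - lo == 94

    def test_point_mass(self):
        lo, hi = hpd_interval(np.full(50, 2.5))
        assert lo == hi == 2.5

    def test_matches_brute_force_windows(self, rng):
        x = np.sort(rng.gamma(2.0, 1.5, size=87))
        k = math.ceil(0.95 * len(x))
        widths = [(x[i + k - 1] - x[i], x[i], x[i + k - 1])
                  for i in range(len(x) - k + 1)]
        _, blo, bhi = min(widths)
        assert hpd_interval(x, 0.95) == (blo, bhi)


class TestChronogram:
    def test_newick_round_trip_ages(self):
        chron = chronogram_from_newick("((a:1,b:1):1.5,(c:2,d:2):0.5);")
        ages = chron.clade_ages()
        assert ages[frozenset(["a", "b"])] == pytest.approx(1.0)
        assert ages[frozenset(["c", "d"])] == pytest.approx(2.0)
        assert chron.root_age == pytest.approx(2.5)

    def test_non_ultrametric_rejected(self):
        with pytest.raises(Exception, match="ultrametric"):
            chronogram_from_newick("((a:1,b:2):1,c:3);")

    def test_build_from_joins(self):
        joins = [(frozenset("ab"), 1.0), (frozenset("abc"), 2.0)]
        chron = build_chronogram(joins, ["a", "b", "c"])
        assert chron.root_age == 2.0


class TestMCC:
    def test_single_sample_is_identity(self):
        sample = {frozenset("ab"): 1.0, frozenset("abc"): 2.0}
        chron = mcc_tree([sample])
        assert chron.clade_ages()[frozenset("ab")] == 1.0
        assert chron.clade_support[frozenset("abc")] == 1.0

    def test_median_node_age(self):
        samples = [{frozenset("ab"): a, frozenset("abc"): 10.0} for a in (1.0, 2.0, 9.0)]
        chron = mcc_tree(samples)
        assert chron.clade_ages()[frozenset("ab")] == 2.0

    def test_unanimous_topology(self):
        samples = [{frozenset("ab"): 1.0 + 0.1 * i, frozenset("abcd"): 3.0,
                    frozenset("cd"): 0.5} for i in range(5)]
        chron = mcc_tree(samples)
        assert set(chron.clade_ages()) == {frozenset("ab"), frozenset("cd"),
                                           frozenset("abcd")}

    def test_empty_rejected(self):
        with pytest.raises(DatingError):
            mcc_tree([])


class TestRelativeDepthScaling:
    def test_linear_scaling(self):
        age, (lo, hi) = scale_relative_node_age(0.5, 10.0, (8.0, 12.0))
        assert (age, lo, hi) == (5.0, 4.0, 6.0)

    def test_identity(self):
        age, ci = scale_relative_node_age(1.0, 7.3, (6.0, 9.0))
        assert age == 7.3 and ci == (6.0, 9.0)

    def test_reference_scaling_to_printed_precision(self):
        # a 26%-relative-depth node under a reference age of 9.7 [8.7, 10.8]
        age, (lo, hi) = scale_relative_node_age(0.26, 9.7, (8.7, 10.8))
        assert round(age, 2) == 2.52
        assert round(lo, 2) == 2.26
        assert round(hi, 2) == 2.81


class TestPriorSampling:
    def test_prior_only_root_marginal_matches_tree_prior(self):
        # 3 taxa, no calibrations: root marginal should follow the
        # order-statistics law g(t) G(t) / Z of the point-process prior
        lam = 0.8
        taxa = ["a", "b", "c"]
        # thinned hard so the retained draws are nearly independent (the KS
        # test assumes iid samples)
        cfg = MCMCConfig(generations=60_000, sample_interval=100, seed=11)
        post = run_dating_mcmc(None, None, None, ClockModel(),
                               TreePriorSpec("birth-death", lam, 0.0),
                               [], [], cfg, prior_only=True, taxa=taxa,
                               tracked_clades={"root": frozenset(taxa)})
        trace, _ = post.post_burnin()
        root = trace["age_root"].to_numpy()
        assert ess(root)[0] > 100  # enough independent information for KS

        def root_cdf(t):
            G = 1.0 - np.exp(-lam * np.asarray(t))
            return G ** 2

        assert kstest(root, root_cdf).pvalue > 0.01

    def test_incompatible_constraints_rejected(self):
        taxa = ["a", "b", "c", "d"]
        cfg = MCMCConfig(generations=100, sample_interval=10, seed=0)
        with pytest.raises(DatingError, match="incompatible|overlap"):
            run_dating_mcmc(None, None, None, ClockModel(), TreePriorSpec(),
                            [], [frozenset("ab"), frozenset("bc")], cfg,
                            prior_only=True, taxa=taxa)

    def test_sampled_trees_respect_constraints_and_ultrametricity(self):
        taxa = list("abcdef")
        constraint = frozenset("abc")
        cfg = MCMCConfig(generations=5_000, sample_interval=50, seed=3)
        post = run_dating_mcmc(None, None, None, ClockModel(),
                               TreePriorSpec("birth-death", 0.7, 0.2),
                               [make_calibration("uniform", {"lower": 4, "upper": 8},
                                                 frozenset(taxa))],
                               [constraint], cfg, prior_only=True, taxa=taxa)
        for sample in post.tree_samples:
            assert constraint in sample
            root_clade = frozenset(taxa)
            for clade, age in sample.items():
                assert age <= sample[root_clade] + 1e-9
                supersets = [c for c in sample if clade < c]
                for sup in supersets:
                    assert sample[sup] >= age - 1e-9
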