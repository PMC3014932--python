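import numpy as np
import pytest

from mitophylo import Alignment, GTRModel
from mitophylo.alignments import PartitionScheme
from mitophylo.likelihood import (
    LikelihoodError,
    PartitionedData,
    TreeLikelihood,
    optimize_parameters,
    tree_loglik,
)
from mitophylo.models import BinaryModel
from mitophylo.simulate import SimulationSpec, simulate_alignment, simulate_chronogram
from mitophylo.trees import parse_newick

from conftest import brute_force_loglik

TOPOLOGIES_4TAXA = [
    "((a:0.12,b:0.23):0.11,c:0.31,d:0.09);",
    "((a:0.12,c:0.23):0.11,b:0.31,d:0.09);",
    "((a:0.12,d:0.23):0.11,b:0.31,c:0.09);",
]


class TestPruningOracle:
    @pytest.mark.parametrize("newick", TOPOLOGIES_4TAXA)
    def test_matches_exhaustive_enumeration(self, newick, small_alignment, gtr_model):
        total, _ = tree_loglik(parse_newick(newick), small_alignment,
                               models={"all": gtr_model})
        oracle = brute_force_loglik(newick, small_alignment, gtr_model)
        assert total == pytest.approx(oracle, abs=1e-10)

    def test_two_taxon_jc_closed_form(self):
        # k differing sites of n; p_diff(t) = 3/4 - 3/4 exp(-4t/3)
        n, k, t = 100, 17, 0.23
        aln = Alignment(["a", "b"], ["A" * n, "C" * k + "A" * (n - k)])
        model = GTRModel(alpha=np.inf, p_inv=0.0)
        total, _ = tree_loglik(parse_newick(f"(a:{t / 2},b:{t / 2});"), aln,
                               models={"all": model})
        p = 0.75 - 0.75 * np.exp(-4.0 * t / 3.0)
        expected = k * np.log(0.25 * p / 3.0) + (n - k) * np.log(0.25 * (1 - p))
        assert total == pytest.approx(expected, abs=1e-8)

    def test_ry_partition_matches_two_state_oracle(self, rng):
        taxa = ["a", "b", "c", "d"]
        mat = ["".join(rng.choice(list("RY?"), p=[0.45, 0.45, 0.1], size=15))
               for _ in taxa]
        aln = Alignment(taxa, mat)
        model = BinaryModel(np.array([0.55, 0.45]), 0.1, 0.8)
        newick = TOPOLOGIES_4TAXA[0]
        total, _ = tree_loglik(parse_newick(newick), aln, models={"all": model})
        oracle = brute_force_loglik(newick, aln, model)
        assert total == pytest.approx(oracle, abs=1e-10)

    def test_all_missing_column_contributes_nothing(self, small_alignment, gtr_model):
        tree = parse_newick(TOPOLOGIES_4TAXA[0])
        base, _ = tree_loglik(tree, small_alignment, models={"all": gtr_model})
        padded = Alignment(small_alignment.taxa,
                           [row + "?" for row in small_alignment.matrix])
        total, _ = tree_loglik(parse_newick(TOPOLOGIES_4TAXA[0]), padded,
                               models={"all": gtr_model})
        assert total == pytest.approx(base, abs=1e-9)


class TestInvariances:
    def test_taxon_reordering(self, small_alignment, gtr_model):
        tree = parse_newick(TOPOLOGIES_4TAXA[0])
        base, _ = tree_loglik(tree, small_alignment, models={"all": gtr_model})
        order = [2, 0, 3, 1]
        shuffled = Alignment([small_alignment.taxa[i] for i in order],
                             [small_alignment.matrix[i] for i in order])
        total, _ = tree_loglik(parse_newick(TOPOLOGIES_4TAXA[0]), shuffled,
                               models={"all": gtr_model})
        assert total == pytest.approx(base, abs=1e-8)

    def test_rerooting_invariance(self, small_alignment, gtr_model):
        # the same unrooted tree written with different basal arrangements
        forms = ["((a:0.12,b:0.23):0.11,c:0.31,d:0.09);",
                 "((c:0.31,(a:0.12,b:0.23):0.11):0.04,d:0.05);",
                 "(a:0.12,(c:0.31,d:0.09):0.11,b:0.23);"]
        vals = [tree_loglik(parse_newick(f), small_alignment,
                            models={"all": gtr_model})[0] for f in forms]
        assert vals[0] == pytest.approx(vals[2], abs=1e-8)

    def test_partitioned_total_is_sum_of_partitions(self, rng, gtr_model):
        taxa = ["a", "b", "c", "d"]
        mat = ["".join(rng.choice(list("ACGT"), size=30)) for _ in taxa]
        aln = Alignment(taxa, mat)
        scheme = PartitionScheme({"x": list(range(1, 16)), "y": list(range(16, 31))})
        m2 = gtr_model.copy()
        m2.alpha = 1.5
        tree = parse_newick(TOPOLOGIES_4TAXA[1])
        total, sw = tree_loglik(tree, aln, scheme,
                                {"x": gtr_model, "y": m2})
        x_total, _ = tree_loglik(parse_newick(TOPOLOGIES_4TAXA[1]),
                                 aln.columns(np.arange(15)), models={"all": gtr_model})
        y_total, _ = tree_loglik(parse_newick(TOPOLOGIES_4TAXA[1]),
                                 aln.columns(np.arange(15, 30)), models={"all": m2})
        assert total == pytest.approx(x_total + y_total, abs=1e-8)
        assert sw.values[sw.mask].sum() == pytest.approx(total, abs=1e-6)

    def test_taxon_mismatch_rejected(self, small_alignment, gtr_model):
        tree = parse_newick("((a:0.1,b:0.1):0.1,c:0.1,e:0.1);")
        with pytest.raises(LikelihoodError):
            tree_loglik(tree, small_alignment, models={"all": gtr_model})


class TestOptimization:
    def test_identical_sequences_collapse_branches(self):
        aln = Alignment(["a", "b", "c", "d"], ["ACGTACGTAC"] * 4)
        tree = parse_newick(TOPOLOGIES_4TAXA[0])
        data = PartitionedData(aln)
        engine = TreeLikelihood(data, tree, {"all": GTRModel(alpha=np.inf)})
        engine.optimize_branch_lengths()
        assert np.all(engine.bl[engine.edge_nodes] <= 1e-6)

    def test_refit_from_optimum_is_fixed_point(self, rng):
        taxa = ["a", "b", "c", "d", "e"]
        chron = simulate_chronogram(SimulationSpec(seed=5, n_taxa=5, birth_rate=0.7))
        model = GTRModel(alpha=0.8)
        spec = SimulationSpec(seed=6, tree_source=chron,
                              partition_lengths={"all": 1500},
                              partition_models={"all": model},
                              rate_multipliers={"all": 1.0},
                              clock_rate=0.05, sigma=0.0)
        aln, _, _ = simulate_alignment(chron, spec)
        tree = parse_newick(chron.tree.as_string(schema="newick",
                                                 unquoted_underscores=True))
        models, tree, lnl1, conv = optimize_parameters(
            tree, aln, None, {"all": model.copy()}, fit_pinv=False, max_passes=6)
        _, _, lnl2, _ = optimize_parameters(
            tree, aln, None, models, fit_pinv=False, max_passes=2)
        assert conv
        assert lnl2 - lnl1 < 0.05
        assert lnl2 >= lnl1 - 1e-6

    def test_simulation_recovery_alpha_and_freqs(self):
        # moderate-size single-partition recovery of alpha and base frequencies
        chron = simulate_chronogram(SimulationSpec(seed=17, n_taxa=8, birth_rate=0.6))
        truth = GTRModel(np.array([1.5, 4.0, 1.0, 1.0, 6.0, 1.0]),
                         np.array([0.3, 0.25, 0.2, 0.25]), 0.0, 0.5)
        spec = SimulationSpec(seed=18, tree_source=chron,
                              partition_lengths={"all": 20000},
                              partition_models={"all": truth},
                              rate_multipliers={"all": 1.0},
                              clock_rate=0.04, sigma=0.0)
        aln, _, _ = simulate_alignment(chron, spec)
        tree = parse_newick(chron.tree.as_string(schema="newick",
                                                 unquoted_underscores=True))
        # fit without an invariant class (the generating model has none;
        # a fixed nonzero p_inv would be absorbed into alpha)
        init = GTRModel(alpha=1.0)
        models, _, _, _ = optimize_parameters(tree, aln, None, {"all": init},
                                              fit_pinv=False, max_passes=6)
        fit = models["all"]
        assert abs(fit.alpha - truth.alpha) / truth.alpha < 0.15
        assert np.all(np.abs(fit.base_freqs - truth.base_freqs) < 0.02)
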