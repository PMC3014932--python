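import numpy as np
import pytest

from mitophylo import GTRModel
from mitophylo.simulate import (
    CANDIDATE_TEMPLATES,
    SimulationSpec,
    expand_candidates,
    make_wg_fixture,
    simulate_alignment,
    simulate_chronogram,
    write_fixture,
)
from mitophylo.chronogram import validate_ultrametric
from mitophylo.trees import parse_newick, same_unrooted_topology


class TestChronogramSimulation:
    def test_ultrametric_with_requested_taxa(self):
        chron = simulate_chronogram(SimulationSpec(seed=1, n_taxa=12,
                                                   birth_rate=0.6, death_rate=0.2))
        assert len(chron.taxa) == 12
        validate_ultrametric(chron.tree)

    def test_yule_root_age_halves_with_doubled_birth_rate(self):
        # root age is the max of n-1 iid Exponential(birth) draws
        def mean_root(birth, seeds):
            ages = [simulate_chronogram(
                SimulationSpec(seed=s, n_taxa=6, birth_rate=birth,
                               death_rate=0.0)).root_age for s in seeds]
            return np.mean(ages)

        slow = mean_root(0.5, range(500))
        fast = mean_root(1.0, range(500, 1000))
        assert abs(slow / fast - 2.0) < 0.3  # ratio 2 within sampling error

    def test_fixed_newick_passthrough(self):
        nwk = "((a:1,b:1):1,(c:1.5,d:1.5):0.5);"
        chron = simulate_chronogram(SimulationSpec(seed=0, tree_source=nwk))
        assert chron.root_age == pytest.approx(2.0)
        assert sorted(chron.taxa) == ["a", "b", "c", "d"]


class TestAlignmentSimulation:
    def test_zero_rate_partition_identical_across_taxa(self):
        chron = simulate_chronogram(SimulationSpec(seed=3, n_taxa=6, birth_rate=0.7))
        spec = SimulationSpec(seed=4, tree_source=chron,
                              partition_lengths={"frozen": 200, "live": 200},
                              partition_models={"frozen": GTRModel(),
                                                "live": GTRModel()},
                              rate_multipliers={"frozen": 0.0, "live": 1.0},
                              clock_rate=0.05, sigma=0.0)
        aln, scheme, _ = simulate_alignment(chron, spec)
        frozen_cols = scheme.zero_based("frozen")
        frozen = {row for row in
                  ("".join(aln.matrix[i][c] for c in frozen_cols)
                   for i in range(aln.ntaxa))}
        assert len(frozen) == 1
        live_cols = scheme.zero_based("live")
        live = {"".join(aln.matrix[i][c] for c in live_cols)
                for i in range(aln.ntaxa)}
        assert len(live) > 1

    def test_two_taxon_identity_matches_jc_closed_form(self):
        d = 0.3  # total path length between the two tips, subst/site
        nwk = f"(a:{d / 2 / 0.05},b:{d / 2 / 0.05});"
        chron = simulate_chronogram(SimulationSpec(seed=0, tree_source=nwk))
        n = 50_000
        spec = SimulationSpec(seed=9, tree_source=chron,
                              partition_lengths={"all": n},
                              partition_models={"all": GTRModel(alpha=np.inf)},
                              rate_multipliers={"all": 1.0},
                              clock_rate=0.05, sigma=0.0)
        aln, _, _ = simulate_alignment(chron, spec)
        expected = 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)
        observed = np.mean(np.frombuffer(aln.matrix[0].encode(), dtype="S1")
                           == np.frombuffer(aln.matrix[1].encode(), dtype="S1"))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 4 * se

    def test_hypervariable_partition_saturates(self):
        fx = make_wg_fixture(seed=5, length_scale=0.25)
        arr = fx.alignment.to_array()
        i, j = fx.alignment.taxa.index("out_vole"), fx.alignment.taxa.index("rsor")
        c1 = fx.wg_scheme.zero_based("codon1")
        hv = np.arange(fx.wg_columns, fx.alignment.ncols)
        p_codon1 = np.mean(arr[i][c1] != arr[j][c1])
        p_hyper = np.mean(arr[i][hv] != arr[j][hv])
        assert p_hyper > 0.55  # near the multi-state saturation ceiling
        assert p_codon1 < 0.30  # codon1 remains far from saturation

    def test_base_composition_tracks_stationary_freqs(self):
        chron = simulate_chronogram(SimulationSpec(seed=6, n_taxa=4, birth_rate=0.8))
        model = GTRModel(base_freqs=np.array([0.4, 0.3, 0.1, 0.2]), alpha=np.inf)
        spec = SimulationSpec(seed=7, tree_source=chron,
                              partition_lengths={"all": 30_000},
                              partition_models={"all": model},
                              rate_multipliers={"all": 1.0},
                              clock_rate=0.02, sigma=0.0)
        aln, _, _ = simulate_alignment(chron, spec)
        counts = np.array([sum(row.count(b) for row in aln.matrix)
                           for b in "ACGT"], dtype=float)
        assert np.all(np.abs(counts / counts.sum() - model.base_freqs) < 0.02)

    def test_partition_streams_regenerate_independently(self):
        chron = simulate_chronogram(SimulationSpec(seed=8, n_taxa=5, birth_rate=0.7))
        kwargs = dict(tree_source=chron,
                      partition_models={"x": GTRModel(), "y": GTRModel()},
                      rate_multipliers={"x": 1.0, "y": 1.0},
                      clock_rate=0.03, sigma=0.0)
        a1, s1, _ = simulate_alignment(chron, SimulationSpec(
            seed=11, partition_lengths={"x": 100, "y": 100}, **kwargs))
        a2, s2, _ = simulate_alignment(chron, SimulationSpec(
            seed=11, partition_lengths={"x": 100, "y": 50}, **kwargs))
        x1 = ["".join(a1.matrix[i][c] for c in s1.zero_based("x")) for i in range(5)]
        x2 = ["".join(a2.matrix[i][c] for c in s2.zero_based("x")) for i in range(5)]
        assert x1 == x2  # partition x unchanged when only y's length changes


class TestWGFixture:
    def test_dimensions_and_taxa(self):
        fx = make_wg_fixture(seed=2, length_scale=0.05)
        assert fx.alignment.ntaxa == 16
        assert fx.wg_columns == sum(fx.wg_scheme.sizes().values())
        assert len(fx.candidates) == 18
        assert sum(r.width for r in fx.regions_3g) > 0

    def test_full_scale_column_counts(self):
        fx = make_wg_fixture(seed=2, length_scale=1.0)
        assert fx.wg_columns == 14471
        assert fx.alignment.ncols == 14471 + 578
        widths = {r.name: r.width for r in fx.regions_3g}
        assert widths == {"cytb": 672, "coi": 702, "dloop": 578}
        assert sum(widths.values()) == 1952

    def test_generating_topology_is_first_candidate(self):
        fx = make_wg_fixture(seed=2, length_scale=0.05)
        gen = parse_newick(fx.chronogram.tree.as_string(
            schema="newick", unquoted_underscores=True))
        assert same_unrooted_topology(gen, parse_newick(fx.candidates["T01"]))
        assert len(CANDIDATE_TEMPLATES) == 18

    def test_deterministic_per_seed(self):
        a = make_wg_fixture(seed=9, length_scale=0.02).alignment
        b = make_wg_fixture(seed=9, length_scale=0.02).alignment
        c = make_wg_fixture(seed=10, length_scale=0.02).alignment
        assert a.matrix == b.matrix
        assert a.matrix != c.matrix

    def test_bundle_round_trips_through_disk(self, tmp_path):
        from mitophylo.alignments import read_alignment

        fx = make_wg_fixture(seed=3, length_scale=0.02)
        write_fixture(fx, str(tmp_path))
        aln, scheme = read_alignment(str(tmp_path / "alignment.nxs"))
        assert aln.matrix == fx.alignment.matrix
        assert set(scheme.partitions) == set(fx.wg_scheme.partitions) | {"hypervar"}
        candidates = (tmp_path / "candidates.nwk").read_text().strip().splitlines()
        assert len(candidates) == 18
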