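"""Synthetic dated trees and partitioned alignments.

The generator emulates the statistical structure of a whole-mitogenome
(~14.5 kb) alignment of 16 murid taxa: protein-coding columns laid out in
codon triplets, RNA stem/loop blocks, and a short hypervariable control-region
block evolving an order of magnitude faster; branch rates follow an
uncorrelated lognormal relaxed clock around a calibrated chronogram. No indels
are simulated — alignments are generated aligned, since alignment estimation
is out of scope.

Seeds propagate hierarchically (bundle seed -> per-partition streams), so any
partition can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignments import Alignment, PartitionScheme, RegionSpec
from .chronogram import Chronogram, build_chronogram, chronogram_from_newick
from .models import BinaryModel, GTRModel, discretize_gamma, eigensystem


@dataclass
class SimulationSpec:
    """Conditions for one simulated dataset.

    ``partition_lengths``/``partition_models``/``rate_multipliers`` are keyed
    by partition name. ``clock_rate`` is in substitutions/site/My for a
    partition with multiplier 1; ``sigma`` is the stdev of log branch-rate
    multipliers (mean fixed at 1). ``seed`` is mandatory.
    """

    seed: int
    n_taxa: int = 16
    tree_source: str | Chronogram | None = None   # newick with ages, or None
    birth_rate: float = 0.5
    death_rate: float = 0.2
    partition_lengths: dict[str, int] = field(default_factory=dict)
    partition_models: dict[str, GTRModel | BinaryModel] = field(default_factory=dict)
    rate_multipliers: dict[str, float] = field(default_factory=dict)
    clock_rate: float = 0.015
    sigma: float = 0.1
    column_layout: list[str] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, length in self.partition_lengths.items():
            if length <= 0:
                raise ValueError(f"partition {name!r}: length must be > 0")
        for name, mult in self.rate_multipliers.items():
            if mult < 0:
                raise ValueError(f"partition {name!r}: multiplier must be >= 0")


def _bd_age_sample(u: np.ndarray, birth: float, death: float) -> np.ndarray:
    """Inverse-CDF sample of the conditioned birth-death node-age density.

    Node ages of the reconstructed process conditioned on the tip count are
    iid with density g(t) = birth * r^2 exp(-rt) / (birth - death exp(-rt))^2,
    r = birth - death (pure-birth: exponential with rate ``birth``).
    """
    if death == 0.0:
        return -np.log1p(-u) / birth
    r = birth - death
    x = birth * (1.0 - u) / (birth - u * death)
    return -np.log(x) / r


def simulate_chronogram(spec: SimulationSpec) -> Chronogram:
    """Ultrametric tree with ``n_taxa`` leaves from the conditioned birth-death
    process (or the fixed dated tree, passed through unchanged)."""
    if isinstance(spec.tree_source, Chronogram):
        return spec.tree_source
    if isinstance(spec.tree_source, str):
        return chronogram_from_newick(spec.tree_source)
    if spec.n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(spec.seed)
    ages = np.sort(_bd_age_sample(rng.random(spec.n_taxa - 1),
                                  spec.birth_rate, spec.death_rate))
    taxa = [f"t{i + 1:02d}" for i in range(spec.n_taxa)]
    lineages = [frozenset([t]) for t in taxa]
    joins: list[tuple[frozenset, float]] = []
    for age in ages:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        merged = lineages[i] | lineages[j]
        lineages = [ln for k, ln in enumerate(lineages) if k not in (i, j)]
        lineages.append(merged)
        joins.append((merged, float(age)))
    return build_chronogram(joins, taxa)


def _draw_states(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw; probs is (nsites, nstates)."""
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(len(probs))
    return (u[:, None] > cum).sum(axis=1)


def _simulate_partition(chron: Chronogram, model, length: int, eff_rate: float,
                        branch_rates: dict[int, float],
                        rng: np.random.Generator) -> dict[str, str]:
    """Evolve one partition along the dated tree; returns taxon -> sequence."""
    states = model.states
    pi = model.base_freqs
    g_rates, _ = discretize_gamma(model.alpha, model.n_cat)
    cats = rng.integers(0, model.n_cat, size=length)
    invariant = rng.random(length) < model.p_inv
    eig = eigensystem(model)
    seqs: dict[str, str] = {}
    root = chron.tree.seed_node
    node_states = {id(root): _draw_states(rng, np.tile(pi, (length, 1)))}
    for node in chron.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        duration = float(node.parent_node.age) - float(node.age)
        t_base = duration * eff_rate * branch_rates[id(node)]
        parent_states = node_states[id(node.parent_node)]
        child_states = parent_states.copy()
        if t_base > 0:
            P = eig.transition_matrices(t_base * g_rates)  # (ncat, ns, ns)
            mobile = ~invariant
            idx = np.where(mobile)[0]
            if len(idx):
                probs = P[cats[idx], parent_states[idx], :]
                child_states[idx] = _draw_states(rng, probs)
        node_states[id(node)] = child_states
        if node.is_leaf():
            seqs[node.taxon.label] = "".join(states[s] for s in child_states)
    return seqs


def simulate_alignment(chron: Chronogram, spec: SimulationSpec
                       ) -> tuple[Alignment, PartitionScheme, dict]:
    """Partitioned alignment evolved along ``chron`` under the spec's models.

    Per-branch rates are drawn once from lognormal(mean 1, sigma) and shared
    by all partitions; each partition then applies its own rate multiplier and
    substitution model. Returns the alignment, its partition scheme and a
    truth record sufficient for parameter- and topology-recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    branch_rates: dict[int, float] = {}
    for node in chron.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if spec.sigma > 0:
            branch_rates[id(node)] = float(np.exp(
                rng.normal(-spec.sigma ** 2 / 2.0, spec.sigma)))
        else:
            branch_rates[id(node)] = 1.0
    taxa = chron.taxa
    blocks: dict[str, dict[str, str]] = {}
    part_seeds = {}
    for k, (name, length) in enumerate(sorted(spec.partition_lengths.items())):
        part_seeds[name] = (spec.seed * 1000 + 7 * k + 1) % (2 ** 31)
        part_rng = np.random.default_rng(part_seeds[name])
        model = spec.partition_models[name]
        mult = spec.rate_multipliers.get(name, 1.0)
        blocks[name] = _simulate_partition(
            chron, model, length, spec.clock_rate * mult, branch_rates, part_rng)
    layout = spec.column_layout
    if layout is None:
        layout = []
        for name, length in spec.partition_lengths.items():
            layout.extend([name] * length)
    counts = {name: 0 for name in spec.partition_lengths}
    parts: dict[str, list[int]] = {name: [] for name in spec.partition_lengths}
    rows = {t: [] for t in taxa}
    for col, name in enumerate(layout, start=1):
        k = counts[name]
        counts[name] += 1
        parts[name].append(col)
        for t in taxa:
            rows[t].append(blocks[name][t][k])
    if counts != dict(spec.partition_lengths):
        raise ValueError("column layout does not match partition lengths")
    aln = Alignment(taxa, ["".join(rows[t]) for t in taxa], list(layout))
    scheme = PartitionScheme(parts)
    truth = {
        "chronogram": chron,
        "branch_rates": {
            frozenset(lf.taxon.label for lf in node.leaf_iter()): branch_rates[id(node)]
            for node in chron.tree.preorder_node_iter() if node.parent_node is not None
        },
        "models": {k: v.copy() for k, v in spec.partition_models.items()},
        "rate_multipliers": dict(spec.rate_multipliers),
        "clock_rate": spec.clock_rate,
        "sigma": spec.sigma,
        "partition_seeds": part_seeds,
        "seed": spec.seed,
    }
    return aln, scheme, truth


# ---------------------------------------------------------------------------
# The 16-taxon whole-genome-style fixture
# ---------------------------------------------------------------------------

#: the 18 candidate arrangements of the ingroup radiation, with the outgroup
#: pair ("Out"), the Asian clade ("AR") and the two-sample leucopus-analog
#: lineage ("Rleu") as labeled placeholders
CANDIDATE_TEMPLATES = {
    "T01": "(Out,(AR,((((((Rsor,Rvil),Rlut),Rtun),Rfus),Rleu),Rpraet)));",
    "T02": "(Out,(AR,((((((Rsor,Rvil),Rlut),Rtun),Rfus),Rpraet),Rleu)));",
    "T03": "(Out,(AR,(((((Rsor,Rvil),Rlut),Rtun),Rfus),(Rleu,Rpraet))));",
    "T04": "(Out,(AR,(((((Rsor,Rvil),(Rlut,Rtun)),Rfus),Rpraet),Rleu)));",
    "T05": "(Out,(AR,((((Rsor,Rvil),(Rtun,Rlut)),Rfus),(Rleu,Rpraet))));",
    "T06": "(Out,(AR,(((((Rsor,Rvil),Rlut),Rtun),(Rleu,Rfus)),Rpraet)));",
    "T07": "(Out,(AR,((((((Rsor,Rvil),Rlut),Rtun),Rleu),Rpraet),Rfus)));",
    "T08": "(Out,(AR,(((((Rsor,Rvil),Rtun),Rlut),(Rfus,Rpraet)),Rleu)));",
    "T09": "(Out,(AR,((((Rsor,Rvil),Rtun),Rlut),((Rleu,Rfus),Rpraet))));",
    "T10": "(Out,(AR,(((Rsor,Rvil),(Rtun,Rlut)),((Rfus,Rpraet),Rleu))));",
    "T11": "(Out,(AR,((((Rsor,Rvil),Rtun),Rlut),((Rleu,Rfus),Rpraet))));",
    "T12": "(Out,(AR,((Rsor,Rvil),((Rlut,Rtun),(Rfus,(Rleu,Rpraet))))));",
    "T13": "(Out,(AR,((((Rsor,Rtun),Rvil),(Rlut,Rfus)),(Rleu,Rpraet))));",
    "T14": "(Out,(AR,(((((Rsor,Rvil),Rleu),Rfus),(Rtun,Rlut)),Rpraet)));",
    "T15": "(Out,(AR,((((Rsor,Rvil),Rlut),Rtun),(Rfus,(Rleu,Rpraet)))));",
    "T16": "(Out,(AR,(((((Rsor,Rvil),Rlut),Rtun),(Rpraet,Rfus)),Rleu)));",
    "T17": "(Out,(AR,((((Rsor,Rlut),Rtun),((Rvil,Rfus),Rpraet)),Rleu)));",
    "T18": "(Out,(AR,((Rsor,Rvil),((Rlut,Rtun),((Rfus,Rpraet),Rleu)))));",
}

#: placeholder/leaf expansions over the fixture's 16 taxa (multi-taxon
#: placeholders first so prefixes never collide)
PLACEHOLDER_EXPANSIONS = {
    "Out": "(out_vole,out_mouse)",
    "AR": "((ar_nor1,ar_nor2),((ar_exu1,ar_exu2),(ar_rat,ar_tan)))",
    "Rleu": "(rleu_a,rleu_b)",
    "Rsor": "rsor", "Rvil": "rvil", "Rlut": "rlut", "Rtun": "rtun",
    "Rfus": "rfus", "Rpraet": "rpraet",
}

OUTGROUP_TAXA = ("out_vole", "out_mouse")
ASIAN_TAXA = ("ar_nor1", "ar_nor2", "ar_exu1", "ar_exu2", "ar_rat", "ar_tan")
AUSTRALO_PAPUAN_TAXA = ("rsor", "rvil", "rlut", "rtun", "rfus",
                        "rleu_a", "rleu_b", "rpraet")

#: generating chronogram: calibration-scale outgroup depths (root ~16.5 My,
#: mouse/rat-analog split 11.65 My) over a shallow two-clade ingroup radiation
FIXTURE_CHRONOGRAM_NEWICK = (
    "(out_vole:16.5,(out_mouse:11.65,("
    "((ar_nor1:0.2,ar_nor2:0.2):2.05,((ar_exu1:0.15,ar_exu2:0.15):1.62,"
    "(ar_rat:0.3,ar_tan:0.3):1.47):0.48):0.45,"
    "((((((rsor:0.49,rvil:0.49):0.35,rlut:0.84):0.11,rtun:0.95):0.4,"
    "rfus:1.35):0.2,(rleu_a:0.6,rleu_b:0.6):0.95):0.11,rpraet:1.66):1.04"
    "):8.95):4.85);"
)

#: partition column counts at scale 1 (coding 3 x 3799 = 11397, stem 1932,
#: loop 1142 -> 14471 columns, plus a 578-column hypervariable block)
FIXTURE_LENGTHS = {"codon1": 3799, "codon2": 3799, "codon3": 3799,
                   "stem": 1932, "loop": 1142, "hypervar": 578}

FIXTURE_MULTIPLIERS = {"codon1": 0.4, "codon2": 0.15, "codon3": 3.5,
                       "stem": 0.3, "loop": 0.7, "hypervar": 12.0}


def fixture_models() -> dict[str, GTRModel]:
    """True per-partition substitution models of the fixture."""
    mito_freqs = np.array([0.34, 0.26, 0.12, 0.28])
    rna_freqs = np.array([0.36, 0.22, 0.18, 0.24])
    ex = np.array([1.5, 8.0, 1.2, 0.9, 12.0, 1.0])
    return {
        "codon1": GTRModel(ex.copy(), mito_freqs.copy(), 0.0, 0.40),
        "codon2": GTRModel(ex.copy(), mito_freqs.copy(), 0.0, 0.30),
        "codon3": GTRModel(ex.copy(), np.array([0.40, 0.28, 0.06, 0.26]), 0.0, 2.0),
        "stem": GTRModel(ex.copy(), rna_freqs.copy(), 0.0, 0.30),
        "loop": GTRModel(ex.copy(), rna_freqs.copy(), 0.0, 0.50),
        "hypervar": GTRModel(ex.copy(), np.array([0.33, 0.30, 0.10, 0.27]), 0.0, 1.0),
    }


def expand_candidates(templates: dict[str, str] | None = None) -> dict[str, str]:
    """Candidate topologies over the 16 fixture taxa (placeholders expanded)."""
    templates = templates or CANDIDATE_TEMPLATES
    out = {}
    for name, newick in templates.items():
        for key, repl in PLACEHOLDER_EXPANSIONS.items():
            newick = newick.replace(key, repl)
        out[name] = newick
    return out


@dataclass
class WGFixture:
    """Synthetic stand-in for the whole-mitogenome study dataset."""

    alignment: Alignment          # full matrix incl. the hypervariable block
    wg_scheme: PartitionScheme    # codon1..3 + stem + loop over the WG columns
    wg_columns: int               # the hypervariable block sits after these
    regions_3g: list[RegionSpec]  # cytb-like, coi-like, hypervariable
    chronogram: Chronogram
    models: dict[str, GTRModel]
    rate_multipliers: dict[str, float]
    candidates: dict[str, str]
    truth: dict
    seed: int

    @property
    def wg_alignment(self) -> Alignment:
        return self.alignment.columns(np.arange(self.wg_columns))


def make_wg_fixture(seed: int, length_scale: float = 1.0,
                    sigma: float = 0.1, clock_rate: float = 0.015) -> WGFixture:
    """Simulate the 16-taxon whole-mitogenome-style bundle.

    ``length_scale`` shrinks every partition proportionally (>= 10 columns
    each) for quick analyses; the generating chronogram, models and candidate
    topology set are unchanged.
    """
    lengths = {name: max(10, int(round(n * length_scale)))
               for name, n in FIXTURE_LENGTHS.items()}
    models = fixture_models()
    chron = chronogram_from_newick(FIXTURE_CHRONOGRAM_NEWICK)
    n_coding = lengths["codon1"]
    layout: list[str] = []
    for _ in range(n_coding):
        layout.extend(["codon1", "codon2", "codon3"])
    layout.extend(["stem"] * lengths["stem"])
    layout.extend(["loop"] * lengths["loop"])
    layout.extend(["hypervar"] * lengths["hypervar"])
    lengths["codon2"] = n_coding
    lengths["codon3"] = n_coding
    spec = SimulationSpec(
        seed=seed, n_taxa=16, tree_source=chron,
        partition_lengths=lengths, partition_models=models,
        rate_multipliers=dict(FIXTURE_MULTIPLIERS),
        clock_rate=clock_rate, sigma=sigma, column_layout=layout,
    )
    aln, scheme, truth = simulate_alignment(chron, spec)
    wg_columns = aln.ncols - lengths["hypervar"]
    wg_parts = {name: cols for name, cols in scheme.partitions.items()
                if name != "hypervar"}
    wg_scheme = PartitionScheme(wg_parts)
    # 3G-style regions: two coding stretches plus the hypervariable block
    w_cytb, w_coi = 672, 702
    w_cytb = min(w_cytb, wg_columns // 4)
    w_coi = min(w_coi, wg_columns // 4)
    start_cytb = wg_columns // 8 + 1
    start_coi = wg_columns // 2 + 1
    regions = [
        RegionSpec("cytb", [(start_cytb, start_cytb + w_cytb - 1)]),
        RegionSpec("coi", [(start_coi, start_coi + w_coi - 1)]),
        RegionSpec("dloop", [(wg_columns + 1, aln.ncols)]),
    ]
    return WGFixture(aln, wg_scheme, wg_columns, regions, chron, models,
                     dict(FIXTURE_MULTIPLIERS), expand_candidates(), truth, seed)


def write_fixture(fixture: WGFixture, directory: str) -> None:
    """Write the bundle: NEXUS alignment with charsets, dated truth tree,
    truth parameters TSV, and the multi-newick candidate set."""
    import os

    from .alignments import write_alignment

    os.makedirs(directory, exist_ok=True)
    full_scheme = PartitionScheme(
        dict(fixture.wg_scheme.partitions) | {
            "hypervar": list(range(fixture.wg_columns + 1,
                                   fixture.alignment.ncols + 1))})
    write_alignment(fixture.alignment, os.path.join(directory, "alignment.nxs"),
                    "nexus", full_scheme)
    with open(os.path.join(directory, "truth_tree.nwk"), "w") as fh:
        fh.write(Chronogram(fixture.chronogram.tree).newick() + "\n")
    with open(os.path.join(directory, "candidates.nwk"), "w") as fh:
        for name, newick in fixture.candidates.items():
            fh.write(f"[&name={name}] {newick}\n")
    with open(os.path.join(directory, "truth_params.tsv"), "w") as fh:
        fh.write("partition\tmultiplier\talpha\tp_inv\tfreqs\n")
        for name, model in fixture.models.items():
            freqs = ",".join(f"{x:.4f}" for x in model.base_freqs)
            fh.write(f"{name}\t{fixture.rate_multipliers[name]}\t"
                     f"{model.alpha}\t{model.p_inv}\t{freqs}\n")
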