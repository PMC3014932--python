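import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from mitophylo import Alignment, GTRModel
from mitophylo.alignments import IUPAC
from mitophylo.models import BinaryModel, build_rate_matrix, discretize_gamma
from mitophylo.trees import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_alignment(rng):
    """4 taxa x 20 columns with gaps, missing data and ambiguity codes."""
    taxa = ["a", "b", "c", "d"]
    chars = list("ACGT-?RN")
    probs = [0.22, 0.22, 0.22, 0.22, 0.04, 0.04, 0.02, 0.02]
    mat = ["".join(rng.choice(chars, p=probs, size=20)) for _ in taxa]
    return Alignment(taxa, mat)


@pytest.fixture
def gtr_model():
    return GTRModel(np.array([1.2, 3.0, 0.8, 1.1, 4.0, 1.0]),
                    np.array([0.3, 0.2, 0.3, 0.2]), 0.15, 0.7)


def brute_force_loglik(newick: str, aln: Alignment, model) -> float:
    """Exhaustive sum over internal-node state assignments (+I+G mixture).

    Independent of the pruning implementation: transition matrices come from
    scipy's matrix exponential and the site likelihood is a literal sum over
    every internal-state combination.
    """
    two_state = isinstance(model, BinaryModel)
    states = "RY" if two_state else "ACGT"
    compat = ({"R": "R", "Y": "Y", "?": "RY", "-": "RY"} if two_state else IUPAC)
    tree = parse_newick(newick)
    Q = build_rate_matrix(model)
    g_rates, _ = discretize_gamma(model.alpha, model.n_cat)
    pi = model.base_freqs
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    taxid = {t: i for i, t in enumerate(aln.taxa)}
    ns = len(states)
    total = 0.0
    for site in range(aln.ncols):
        cat_liks = []
        for r in g_rates:
            P = {id(n): expm(Q * r * (n.edge.length or 0.0)) for n in nodes}
            site_l = 0.0
            for assign in itertools.product(range(ns), repeat=len(internals)):
                amap = {id(n): s for n, s in zip(internals, assign)}
                p = pi[amap[id(tree.seed_node)]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    sp = amap[id(n.parent_node)]
                    if n.is_leaf():
                        ch = aln.matrix[taxid[n.taxon.label]][site]
                        obs = compat.get(ch, states)
                        p *= sum(P[id(n)][sp, states.index(b)] for b in obs)
                    else:
                        p *= P[id(n)][sp, amap[id(n)]]
                site_l += p
            cat_liks.append(site_l)
        l_var = np.mean(cat_liks) * (1 - model.p_inv)
        l_inv = sum(
            pi[x] * np.prod([1.0 if states[x] in compat.get(aln.matrix[t][site], states)
                             else 0.0 for t in range(aln.ntaxa)])
            for x in range(ns))
        total += np.log(model.p_inv * l_inv + l_var)
    return total
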