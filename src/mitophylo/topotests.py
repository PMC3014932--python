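"""Candidate-topology evaluation from sitewise log-likelihoods.

Builds the topologies-by-sites log-likelihood matrix, then applies RELL
resampling (bootstrap of sitewise log-likelihoods without re-optimization),
the Kishino-Hasegawa paired-sites test, and the approximately unbiased test
(multiscale RELL with a probit-scale curve fit correcting selection bias).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .alignments import Alignment, PartitionScheme
from .likelihood import PartitionedData, TreeLikelihood
from .trees import parse_newick

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))


class TopoTestError(ValueError):
    pass


@dataclass
class SitewiseLLMatrix:
    """Per-site log-likelihoods: rows = candidate topologies, columns = sites.

    Sites appear in alignment order (restricted to columns covered by the
    partition scheme). ``totals`` are row sums; ``delta`` is lnL distance to
    the best topology (0 for the best).
    """

    names: list[str]
    matrix: np.ndarray
    partition_labels: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.names):
            raise TopoTestError("matrix must be (n_topologies, n_sites)")

    @property
    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def delta(self) -> np.ndarray:
        totals = self.totals
        return totals.max() - totals

    @property
    def best(self) -> str:
        return self.names[int(np.argmax(self.totals))]

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.matrix.T, columns=self.names)
        df.insert(0, "site", np.arange(1, self.matrix.shape[1] + 1))
        if self.partition_labels:
            df.insert(1, "partition", self.partition_labels)
        df.to_csv(path, sep="\t", index=False)


def sitewise_matrix(candidates: dict[str, str | dendropy.Tree],
                    alignment: Alignment, scheme: PartitionScheme | None = None,
                    models: dict | None = None, optimize_branch_lengths: bool = True,
                    bl_tol: float = 1e-3, max_sweeps: int = 30) -> SitewiseLLMatrix:
    """Sitewise log-likelihood matrix over named candidate topologies.

    Branch lengths are optimized per topology (substitution parameters are
    taken as given, fitted upstream on the ML topology). All candidates must
    share the alignment's leaf set.
    """
    if not candidates:
        raise TopoTestError("no candidate topologies")
    data = PartitionedData(alignment, scheme)
    if models is None:
        models = data.default_models()
    ns = dendropy.TaxonNamespace(alignment.taxa)
    rows, names = [], []
    labels: list[str | None] | None = None
    for name, tree in candidates.items():
        if isinstance(tree, str):
            tree = parse_newick(tree, taxon_namespace=ns)
        if sorted(lf.taxon.label for lf in tree.leaf_node_iter()) != sorted(alignment.taxa):
            raise TopoTestError(f"candidate {name!r}: leaf set mismatch")
        engine = TreeLikelihood(data, tree, models)
        if optimize_branch_lengths:
            engine.optimize_branch_lengths(tol=bl_tol, max_sweeps=max_sweeps)
        values, mask = engine.sitewise()
        rows.append(values[mask])
        names.append(name)
        if labels is None:
            all_labels: list[str | None] = [None] * alignment.ncols
            for part in data.partitions:
                for c in part.cols:
                    all_labels[c] = part.name
            labels = [lab for lab, m in zip(all_labels, mask) if m]
    return SitewiseLLMatrix(names, np.vstack(rows), labels or [])


def rell_resample(matrix: SitewiseLLMatrix, n_reps: int = 10000, seed: int = 0,
                  scale: float = 1.0) -> np.ndarray:
    """RELL replicate totals, shape (n_reps, n_topologies).

    Sites are resampled with replacement; at ``scale`` r the replicate draws
    round(r * n) sites but totals are rescaled to the original n so replicate
    totals are comparable across scales.
    """
    if n_reps < 1:
        raise TopoTestError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n_sites = matrix.matrix.shape[1]
    m = max(1, int(round(scale * n_sites)))
    counts = rng.multinomial(m, np.full(n_sites, 1.0 / n_sites), size=n_reps)
    totals = counts @ matrix.matrix.T  # (n_reps, n_topologies)
    return totals * (n_sites / m)


def kh_test(matrix: SitewiseLLMatrix, topo_a: str, topo_b: str,
            n_reps: int = 10000, seed: int = 0) -> float:
    """Kishino-Hasegawa paired-sites test via RELL.

    One-sided p-value for the worse of the two topologies under the centered
    null of equal expected log-likelihood. Identical rows (or A = B) give 1.
    """
    d = matrix.row(topo_a) - matrix.row(topo_b)
    observed = float(d.sum())
    if np.allclose(d, 0.0):
        return 1.0
    rng = np.random.default_rng(seed)
    n = len(d)
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_reps)
    reps = counts @ d
    centered = reps - reps.mean()
    return float(np.mean(centered >= abs(observed)))


def au_test(matrix: SitewiseLLMatrix, scales: tuple[float, ...] = DEFAULT_SCALES,
            n_reps_per_scale: int = 10000, seed: int = 0) -> dict[str, float]:
    """Approximately unbiased p-value per topology (multiscale RELL).

    At each relative sample size r the bootstrap proportion bp_r of a topology
    being best is probit-transformed, z_r = Phi^-1(1 - bp_r), and the
    signed-distance/curvature model z_r = d*sqrt(r) + c/sqrt(r) is fitted by
    weighted least squares (delta-method weights); p_AU = 1 - Phi(d - c).
    Proportions of exactly 0 or 1 are clamped to 1/(2B) before the transform.
    """
    if len(matrix.names) < 2:
        return {name: 1.0 for name in matrix.names}
    if np.allclose(matrix.matrix, matrix.matrix[0][None, :]):
        return {name: 1.0 for name in matrix.names}
    scales = tuple(scales)
    if not (min(scales) <= 1.0 <= max(scales)):
        raise TopoTestError("scale grid must span 1.0")
    rng = np.random.default_rng(seed)
    ntopo = len(matrix.names)
    bp = np.zeros((len(scales), ntopo))
    for si, r in enumerate(scales):
        totals = rell_resample(matrix, n_reps_per_scale,
                               seed=int(rng.integers(2 ** 31)), scale=r)
        # ties (e.g. duplicated topologies) share the win equally
        is_best = np.isclose(totals, totals.max(axis=1, keepdims=True),
                             rtol=0.0, atol=1e-9)
        bp[si] = (is_best / is_best.sum(axis=1, keepdims=True)).sum(axis=0) \
            / n_reps_per_scale
    eps = 1.0 / (2.0 * n_reps_per_scale)
    bp_c = np.clip(bp, eps, 1.0 - eps)
    z = norm.ppf(1.0 - bp_c)  # (nscales, ntopo)
    sq = np.sqrt(np.asarray(scales))
    X = np.column_stack([sq, 1.0 / sq])
    wins = np.round(bp * n_reps_per_scale)
    out: dict[str, float] = {}
    for t, name in enumerate(matrix.names):
        usable = (bp[:, t] > 0.0) & (bp[:, t] < 1.0)
        if usable.sum() == 0:
            # never (or always) best at every scale: no curve to fit
            out[name] = eps if bp[:, t].mean() < 0.5 else 1.0 - eps
            continue
        if usable.sum() >= 2:
            # probit-scale weighted least squares start (delta-method weights)
            w = n_reps_per_scale * norm.pdf(z[usable, t]) ** 2 \
                / (bp_c[usable, t] * (1.0 - bp_c[usable, t]))
            beta, *_ = np.linalg.lstsq(np.sqrt(w)[:, None] * X[usable],
                                       np.sqrt(w) * z[usable, t], rcond=None)
        else:
            beta = np.array([z[usable, t].mean(), 0.0])
        # refine by binomial maximum likelihood across *all* scales, which
        # uses zero-win scales as censoring information without clamping
        k = wins[:, t]
        B = n_reps_per_scale

        def nll(params):
            x = X @ params
            return -float(np.sum(k * norm.logsf(x) + (B - k) * norm.logcdf(x)))

        res = minimize(nll, beta, method="Nelder-Mead",
                       options={"maxiter": 400, "xatol": 1e-6, "fatol": 1e-8})
        d_hat, c_hat = res.x if res.fun <= nll(beta) else beta
        out[name] = float(np.clip(1.0 - norm.cdf(d_hat - c_hat), 0.0, 1.0))
    return out


def run_topology_tests(candidates: dict[str, str | dendropy.Tree],
                       alignment: Alignment, scheme: PartitionScheme | None = None,
                       models: dict | None = None, n_reps: int = 10000,
                       scales: tuple[float, ...] = DEFAULT_SCALES,
                       seed: int = 0) -> pd.DataFrame:
    """Full candidate-set evaluation: lnL, delta-lnL, AU and KH p-values.

    KH compares each topology against the maximum-likelihood one (the ML
    topology itself gets p = 1 by convention).
    """
    matrix = sitewise_matrix(candidates, alignment, scheme, models)
    p_au = au_test(matrix, scales, n_reps, seed=seed)
    best = matrix.best
    rows = []
    for name, total, delta in zip(matrix.names, matrix.totals, matrix.delta):
        p_kh = 1.0 if name == best else kh_test(matrix, best, name, n_reps, seed)
        rows.append({"topology": name, "lnL": total, "delta": delta,
                     "p_AU": p_au[name], "p_KH": p_kh})
    return pd.DataFrame(rows).sort_values("delta").reset_index(drop=True)
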