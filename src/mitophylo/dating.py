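"""Calibrated relaxed-clock Bayesian divergence dating.

The model: a rooted dated tree with node ages in Mya; branch substitution
rates are independent lognormal multipliers with mean 1 (uncorrelated relaxed
clock) around a base clock rate; per-partition relative rates scale the clock
for heterogeneous partitions. Node-age priors combine a tree prior
(conditioned birth-death point process, or constant-size coalescent) with
fossil-style calibration densities on named clades. Calibrated nodes take
*only* their calibration density under the birth-death prior (conditional
construction), so sampling the prior really does return the stated
calibration distribution at those nodes; under the coalescent (which does not
factorize over nodes) calibrations multiply the full density.

MCMC moves: scale moves on ages/rates/hyperparameters, uniform node-age
slides, whole-tree scaling, and a constrained narrow exchange for topology.
All sampled trees satisfy every monophyly constraint; calibrated clades are
constrained automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kstest, lognorm, norm, truncnorm
from statsmodels.tsa.stattools import acf

from .alignments import Alignment, PartitionScheme
from .chronogram import Chronogram, build_chronogram
from .likelihood import PartitionedData
from .models import discretize_gamma, eigensystem

_Z95 = norm.ppf(0.975)  # 1.959964...


class DatingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Calibrations
# ---------------------------------------------------------------------------

@dataclass
class CalibrationPrior:
    """Age prior on the MRCA of a clade, in Mya.

    Families: ``normal-from-central95`` (central 95% between the two bounds,
    truncated at 0 and renormalized), ``uniform``, and
    ``lognormal-from-median-CI`` (log-scale location at ln median; scale the
    least-squares match of the central 95% to the given CI).
    """

    clade: frozenset
    family: str
    mean: float = 0.0
    sd: float = 1.0
    lower: float = 0.0
    upper: float = math.inf

    def logpdf(self, t: float) -> float:
        if t <= 0:
            return -math.inf
        if self.family == "uniform":
            if self.lower <= t <= self.upper:
                return -math.log(self.upper - self.lower)
            return -math.inf
        if self.family == "normal":
            a = (0.0 - self.mean) / self.sd
            return float(truncnorm.logpdf(t, a, math.inf,
                                          loc=self.mean, scale=self.sd))
        if self.family == "lognormal":
            return float(lognorm.logpdf(t, self.sd, scale=math.exp(self.mean)))
        raise DatingError(f"unknown family {self.family!r}")

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp([self.logpdf(x) for x in t]) if t.ndim else math.exp(self.logpdf(float(t)))

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "uniform":
            return np.clip((t - self.lower) / (self.upper - self.lower), 0, 1)
        if self.family == "normal":
            a = (0.0 - self.mean) / self.sd
            return truncnorm.cdf(t, a, math.inf, loc=self.mean, scale=self.sd)
        return lognorm.cdf(t, self.sd, scale=math.exp(self.mean))

    def median(self) -> float:
        if self.family == "uniform":
            return 0.5 * (self.lower + self.upper)
        if self.family == "normal":
            a = (0.0 - self.mean) / self.sd
            return float(truncnorm.median(a, math.inf, loc=self.mean, scale=self.sd))
        return math.exp(self.mean)

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "uniform":
            return float(rng.uniform(self.lower, self.upper))
        if self.family == "normal":
            a = (0.0 - self.mean) / self.sd
            return float(truncnorm.rvs(a, math.inf, loc=self.mean, scale=self.sd,
                                       random_state=rng))
        return float(lognorm.rvs(self.sd, scale=math.exp(self.mean),
                                 random_state=rng))


def make_calibration(family: str, params: dict, clade: frozenset | None = None
                     ) -> CalibrationPrior:
    """Build a calibration prior.

    ``normal-from-central95``: params lower/upper are the central-95% bounds.
    ``uniform``: params lower/upper. ``lognormal-from-median-CI``: params
    median, lower, upper (the 95% CI to match).
    """
    clade = frozenset(clade or [])
    if family == "normal-from-central95":
        lo, hi = float(params["lower"]), float(params["upper"])
        if hi <= lo:
            raise DatingError("inverted bounds")
        return CalibrationPrior(clade, "normal",
                                mean=0.5 * (lo + hi), sd=(hi - lo) / (2 * _Z95))
    if family == "uniform":
        lo, hi = float(params["lower"]), float(params["upper"])
        if hi <= lo:
            raise DatingError("inverted bounds")
        return CalibrationPrior(clade, "uniform", lower=lo, upper=hi)
    if family == "lognormal-from-median-CI":
        med, lo, hi = (float(params["median"]), float(params["lower"]),
                       float(params["upper"]))
        if not (0 < lo < med < hi):
            raise DatingError("need 0 < lower < median < upper")
        mu = math.log(med)
        # least-squares match of (mu - z sd, mu + z sd) to (ln lo, ln hi)
        # with the location pinned at ln median
        sd = ((mu - math.log(lo)) + (math.log(hi) - mu)) / (2 * _Z95)
        return CalibrationPrior(clade, "lognormal", mean=mu, sd=sd)
    raise DatingError(f"unknown calibration family {family!r}")


def calibration_from_samples(samples: np.ndarray, clade: frozenset | None = None
                             ) -> CalibrationPrior:
    """Lognormal calibration summarizing a posterior sample of ages (used to
    carry a root age estimate from one analysis into a constrained re-run)."""
    med = float(np.median(samples))
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return make_calibration("lognormal-from-median-CI",
                            {"median": med, "lower": lo, "upper": hi}, clade)


# ---------------------------------------------------------------------------
# Tree priors
# ---------------------------------------------------------------------------

@dataclass
class TreePriorSpec:
    """Node-age prior process: conditioned birth-death or constant coalescent."""

    kind: str = "birth-death"   # or "coalescent"
    birth_rate: float = 0.5
    death_rate: float = 0.0
    pop_size: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("birth-death", "coalescent"):
            raise DatingError(f"unknown tree prior {self.kind!r}")
        if self.kind == "birth-death" and self.birth_rate <= self.death_rate:
            raise DatingError("need birth rate > death rate")
        if self.pop_size <= 0 or self.birth_rate <= 0 or self.death_rate < 0:
            raise DatingError("rates/size must be positive")


def _bd_log_g(t: np.ndarray, birth: float, death: float) -> np.ndarray:
    """Log node-age density of the conditioned reconstructed birth-death
    process: g(t) = birth * r^2 e^{-rt} / (birth - death e^{-rt})^2, a proper
    density on (0, inf); pure birth reduces to Exponential(birth)."""
    t = np.asarray(t, dtype=float)
    r = birth - death
    with np.errstate(divide="ignore"):
        return (np.log(birth) + 2 * np.log(r) - r * t
                - 2 * np.log(birth - death * np.exp(-r * t)))


def tree_prior_logdensity(tree_ages, spec: TreePriorSpec) -> float:
    """Log-density of a dated tree's internal node ages under the tree prior.

    ``tree_ages`` is a Chronogram or a sequence of the n-1 internal node ages
    (leaves at age 0). Coalescent: sum over inter-event intervals of
    -k(k-1)dt/(2N), minus (n-1) ln N. Birth-death: sum of log g over nodes.
    """
    if isinstance(tree_ages, Chronogram):
        ages = np.array(sorted(tree_ages.clade_ages().values()))
    else:
        ages = np.sort(np.asarray(list(tree_ages), dtype=float))
    if np.any(ages < 0):
        raise DatingError("negative node age")
    n = len(ages) + 1
    if spec.kind == "birth-death":
        return float(np.sum(_bd_log_g(ages, spec.birth_rate, spec.death_rate)))
    N = spec.pop_size
    out = -(n - 1) * math.log(N)
    times = np.concatenate([[0.0], ages])
    k = n
    for i in range(1, len(times)):
        dt = times[i] - times[i - 1]
        out -= k * (k - 1) * dt / (2.0 * N)
        k -= 1
    return float(out)


# ---------------------------------------------------------------------------
# Clock and MCMC configuration
# ---------------------------------------------------------------------------

@dataclass
class ClockModel:
    """Uncorrelated lognormal clock: independent branch-rate multipliers with
    mean 1 and log-sd sigma (estimated unless ``sample_sigma`` is off)."""

    kind: str = "ucln"
    rate_init: float = 0.01          # subst/site/My for the reference partition
    sigma_init: float = 0.1
    sample_sigma: bool = True
    sigma_prior_mean: float = 0.5    # exponential hyperprior on sigma


@dataclass
class MCMCConfig:
    generations: int = 100_000
    sample_interval: int = 100
    burnin: int | None = None        # generations; None -> plateau rule
    seed: int = 0
    n_chains: int = 1                # Metropolis-coupled chains (1 = cold only)
    heat_delta: float = 0.1
    proposal_weights: dict[str, float] = field(default_factory=dict)
    constraints: list[frozenset] = field(default_factory=list)
    sample_submodel: bool = True     # scale moves on per-partition alpha

    def __post_init__(self) -> None:
        if self.burnin is not None and self.burnin >= self.generations:
            raise DatingError("burnin must be below the generation count")


@dataclass
class PosteriorSample:
    """MCMC output: parameter trace, sampled dated trees, config echo."""

    trace: pd.DataFrame
    tree_samples: list[dict[frozenset, float]]   # clade -> age per sample
    config: MCMCConfig
    burnin_index: int                            # samples to drop

    def post_burnin(self) -> tuple[pd.DataFrame, list[dict[frozenset, float]]]:
        return (self.trace.iloc[self.burnin_index:].reset_index(drop=True),
                self.tree_samples[self.burnin_index:])

    def ages_of(self, clade: frozenset) -> np.ndarray:
        _, trees = self.post_burnin()
        vals = []
        for sample in trees:
            if clade in sample:
                vals.append(sample[clade])
            else:  # MRCA of a non-monophyletic group: smallest superset
                supersets = [c for c in sample if clade <= c]
                vals.append(sample[min(supersets, key=len)])
        return np.asarray(vals)


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

class _State:
    """One chain state over an indexed rooted binary tree."""

    __slots__ = ("parent", "children", "ages", "rates", "mu", "sigma",
                 "part_rates", "alphas", "ln_like", "ln_prior")

    def __init__(self, parent, children, ages, rates, mu, sigma, part_rates, alphas):
        self.parent = parent
        self.children = children
        self.ages = ages
        self.rates = rates
        self.mu = mu
        self.sigma = sigma
        self.part_rates = part_rates
        self.alphas = alphas
        self.ln_like = -math.inf
        self.ln_prior = -math.inf

    def copy(self) -> "_State":
        s = _State(self.parent.copy(), [list(c) for c in self.children],
                   self.ages.copy(), self.rates.copy(), self.mu, self.sigma,
                   dict(self.part_rates), dict(self.alphas))
        s.ln_like, s.ln_prior = self.ln_like, self.ln_prior
        return s


class DatingSampler:
    """Metropolis-Hastings sampler for the calibrated relaxed-clock model."""

    DEFAULT_WEIGHTS = {
        "age_slide": 25.0, "root_scale": 10.0, "tree_scale": 5.0,
        "subtree_scale": 10.0, "up_down": 10.0, "age_rate_slide": 20.0,
        "rate_scale": 20.0, "mu_scale": 5.0, "sigma_scale": 5.0,
        "alpha_scale": 3.0, "part_rate_scale": 5.0, "narrow_exchange": 15.0,
        "calibration_draw": 8.0,
    }

    def __init__(self, alignment: Alignment | None, scheme: PartitionScheme | None,
                 models: dict | None, clock: ClockModel, tree_prior: TreePriorSpec,
                 calibrations: list[CalibrationPrior], config: MCMCConfig,
                 prior_only: bool = False, start: Chronogram | None = None,
                 taxa: list[str] | None = None):
        self.clock = clock
        self.tree_prior = tree_prior
        self.calibrations = list(calibrations)
        self.config = config
        self.prior_only = prior_only or alignment is None
        self.rng = np.random.default_rng(config.seed)
        if alignment is not None:
            self.data = PartitionedData(alignment, scheme)
            self.taxa = list(alignment.taxa)
            self.models = models or self.data.default_models()
            self.part_names = [p.name for p in self.data.partitions]
            self._eigs = {name: eigensystem(self.models[name])
                          for name in self.part_names}
        else:
            if taxa is None:
                raise DatingError("prior-only sampling needs an explicit taxon list")
            self.data = None
            self.taxa = list(taxa)
            self.models = {}
            self.part_names = []
            self._eigs = {}
        self.ntaxa = len(self.taxa)
        self.taxon_index = {t: i for i, t in enumerate(self.taxa)}
        self.constraints = [frozenset(c) for c in config.constraints]
        for cal in self.calibrations:
            if cal.clade and cal.clade not in self.constraints \
                    and len(cal.clade) < self.ntaxa:
                self.constraints.append(cal.clade)
        self._check_constraints_compatible()
        self.weights = dict(self.DEFAULT_WEIGHTS)
        self.weights.update(config.proposal_weights)
        if self.ntaxa <= 3:
            self.weights["narrow_exchange"] = 0.0
        self.state = self._initial_state(start)
        self._score(self.state)
        if not np.isfinite(self.state.ln_prior):
            raise DatingError("initial state has zero prior probability")

    # -- setup --------------------------------------------------------------

    def _check_constraints_compatible(self) -> None:
        taxa = set(self.taxa)
        for c in self.constraints:
            if not c <= taxa:
                raise DatingError(f"constraint references unknown taxa: {sorted(c - taxa)}")
        for a in self.constraints:
            for b in self.constraints:
                if a is not b and a & b and not (a <= b or b <= a):
                    raise DatingError("incompatible (overlapping, non-nested) constraints")

    def _initial_state(self, start: Chronogram | None) -> _State:
        nnodes = 2 * self.ntaxa - 1
        parent = np.full(nnodes, -1, dtype=int)
        children: list[list[int]] = [[] for _ in range(nnodes)]
        ages = np.zeros(nnodes)
        if start is not None:
            joins = sorted(start.clade_ages().items(), key=lambda kv: len(kv[0]))
            groups = {frozenset([t]): i for i, t in enumerate(self.taxa)}
            nxt = self.ntaxa
            for clade, age in joins:
                kids = [g for g in groups if g < clade]
                kids = [g for g in kids if not any(g < other for other in kids)]
                node = nxt
                nxt += 1
                for g in kids:
                    idx = groups.pop(g)
                    parent[idx] = node
                    children[node].append(idx)
                ages[node] = age
                groups[clade] = node
        else:
            nxt = self.ntaxa

            def resolve(group: list[int]) -> int:
                nonlocal nxt
                nodes = list(group)
                while len(nodes) > 1:
                    i, j = sorted(self.rng.choice(len(nodes), 2, replace=False))
                    node = nxt
                    nxt += 1
                    parent[nodes[i]] = node
                    parent[nodes[j]] = node
                    children[node] = [nodes[i], nodes[j]]
                    nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [node]
                return nodes[0]

            def build(taxset: frozenset) -> int:
                inner = [c for c in self.constraints if c < taxset]
                maximal = [c for c in inner if not any(c < o for o in inner)]
                covered = frozenset().union(*maximal) if maximal else frozenset()
                groups = [build(c) for c in maximal]
                groups += [self.taxon_index[t] for t in sorted(taxset - covered)]
                return resolve(groups)

            root = build(frozenset(self.taxa))
            # top-down age assignment honoring calibration medians
            cal_by_clade = {cal.clade: cal for cal in self.calibrations}
            leafsets = self._leaf_sets(parent, children)
            order = sorted(range(self.ntaxa, nnodes),
                           key=lambda v: -len(leafsets[v]))
            root_cal = cal_by_clade.get(frozenset(self.taxa))
            ages[root] = root_cal.median() if root_cal else \
                (len(self.taxa) / self.tree_prior.birth_rate
                 if self.tree_prior.kind == "birth-death" else 2.0 * self.tree_prior.pop_size)
            for v in order:
                if v == root:
                    continue
                pa = ages[parent[v]]
                cal = cal_by_clade.get(leafsets[v])
                if cal is not None:
                    ages[v] = min(cal.median(), 0.95 * pa)
                else:
                    ages[v] = pa * self.rng.uniform(0.4, 0.8)
        rates = np.ones(nnodes)
        part_rates = {name: 1.0 for name in self.part_names}
        alphas = {name: self.models[name].alpha for name in self.part_names}
        return _State(parent, children, ages, rates, self.clock.rate_init,
                      self.clock.sigma_init, part_rates, alphas)

    # -- bookkeeping --------------------------------------------------------

    def _root(self, state: _State) -> int:
        return int(np.where(state.parent == -1)[0][0])

    def _leaf_sets(self, parent, children) -> dict[int, frozenset]:
        nnodes = len(parent)
        out: dict[int, frozenset] = {}
        order = self._postorder(parent, children)
        for v in order:
            if v < self.ntaxa:
                out[v] = frozenset([self.taxa[v]])
            else:
                out[v] = frozenset().union(*(out[c] for c in children[v]))
        return out

    def _postorder(self, parent, children) -> list[int]:
        root = int(np.where(parent == -1)[0][0])
        order, stack = [], [root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(children[v])
        return order[::-1]

    def _satisfies_constraints(self, state: _State) -> bool:
        if not self.constraints:
            return True
        sets = set(self._leaf_sets(state.parent, state.children).values())
        return all(c in sets for c in self.constraints)

    # -- posterior ----------------------------------------------------------

    def _log_prior(self, state: _State) -> float:
        # hard support constraint: every parent strictly older than children
        for v in range(len(state.parent)):
            p = state.parent[v]
            if p >= 0 and state.ages[p] <= state.ages[v]:
                return -math.inf
        if np.any(state.ages[self.ntaxa:] <= 0):
            return -math.inf
        leafsets = self._leaf_sets(state.parent, state.children)
        cal_by_clade = {cal.clade: cal for cal in self.calibrations}
        internal = [v for v in range(self.ntaxa, len(state.parent))]
        lp = 0.0
        calibrated_ages: set[int] = set()
        for v in internal:
            cal = cal_by_clade.get(leafsets[v])
            if cal is not None:
                lp += cal.logpdf(state.ages[v])
                calibrated_ages.add(v)
        if not np.isfinite(lp):
            return -math.inf
        if self.tree_prior.kind == "birth-death":
            free = [state.ages[v] for v in internal if v not in calibrated_ages]
            if free:
                lp += float(np.sum(_bd_log_g(np.array(free),
                                             self.tree_prior.birth_rate,
                                             self.tree_prior.death_rate)))
        else:
            lp += tree_prior_logdensity(state.ages[internal], self.tree_prior)
        # relaxed-clock branch rates: lognormal, mean 1
        s = state.sigma
        if s > 0:
            logr = np.log(state.rates)
            mask = np.ones(len(state.rates), dtype=bool)
            mask[self._root(state)] = False
            mask[:self.ntaxa] = True  # leaves have branches too
            mask_idx = np.where(mask)[0]
            z = (logr[mask_idx] + s * s / 2.0) / s
            lp += float(np.sum(-0.5 * z * z - math.log(s)
                               - 0.5 * math.log(2 * math.pi) - logr[mask_idx]))
        # hyperpriors
        lp += -state.sigma / self.clock.sigma_prior_mean
        lp += norm.logpdf(math.log(state.mu), math.log(self.clock.rate_init), 3.0)
        for name in self.part_names:
            if name != (self.part_names[0] if self.part_names else None):
                lp += norm.logpdf(math.log(state.part_rates[name]), 0.0, 3.0)
            lp += norm.logpdf(math.log(state.alphas[name]), 0.0, 2.0)
        return float(lp)

    def _log_likelihood(self, state: _State) -> float:
        if self.prior_only:
            return 0.0
        order = self._postorder(state.parent, state.children)
        total = 0.0
        durations = np.zeros(len(state.parent))
        for v in range(len(state.parent)):
            p = state.parent[v]
            if p >= 0:
                durations[v] = state.ages[p] - state.ages[v]
        if np.any(durations < -1e-9):
            return -math.inf
        base_bl = np.maximum(durations, 0.0) * state.rates * state.mu
        for part in self.data.partitions:
            model = self.models[part.name]
            eig = self._eigs[part.name]
            g_rates, _ = discretize_gamma(state.alphas[part.name], model.n_cat)
            bl = base_bl * state.part_rates[part.name]
            P = eig.transition_matrices(np.outer(bl, g_rates))
            ncat = len(g_rates)
            npat, ns = part.leaf.shape[1], part.nstates
            partial = {}
            log_scale = {}
            for v in order:
                if v < self.ntaxa:
                    partial[v] = np.broadcast_to(part.leaf[v][None], (ncat, npat, ns))
                    log_scale[v] = 0.0
                    continue
                acc = np.ones((ncat, npat, ns))
                sc = 0.0
                for c in state.children[v]:
                    acc = acc * np.einsum("cij,cpj->cpi", P[c], partial[c])
                    sc = sc + log_scale[c]
                m = np.maximum(acc.max(axis=(0, 2)), 1e-300)
                partial[v] = acc / m[None, :, None]
                log_scale[v] = sc + np.log(m)
            root = order[-1]
            l_cat = partial[root] @ model.base_freqs
            p_inv = model.p_inv
            l_var = l_cat.mean(axis=0) * (1.0 - p_inv)
            with np.errstate(divide="ignore"):
                lv = np.log(np.maximum(l_var, 0.0)) + log_scale[root]
                if p_inv > 0:
                    prod = np.prod(part.leaf, axis=0) @ model.base_freqs
                    lv = np.logaddexp(np.log(np.maximum(p_inv * prod, 0.0)), lv)
            total += float(np.dot(part.weights, lv))
        return total

    #: proposals that provably leave the data likelihood unchanged
    LIKELIHOOD_INVARIANT = frozenset({"sigma_scale", "age_rate_slide"})

    def _score(self, state: _State, keep_likelihood: float | None = None) -> None:
        state.ln_prior = self._log_prior(state)
        if not np.isfinite(state.ln_prior):
            state.ln_like = -math.inf
        elif keep_likelihood is not None:
            state.ln_like = keep_likelihood
        else:
            state.ln_like = self._log_likelihood(state)

    # -- proposals ----------------------------------------------------------

    def _propose(self, state: _State, kind: str) -> tuple[_State, float] | None:
        rng = self.rng
        new = state.copy()
        root = self._root(state)
        internal = np.arange(self.ntaxa, len(state.parent))
        if kind == "age_slide":
            cand = [v for v in internal if v != root]
            if not cand:
                return None
            v = int(rng.choice(cand))
            lo = max(state.ages[c] for c in state.children[v])
            hi = state.ages[state.parent[v]]
            new.ages[v] = rng.uniform(lo, hi)
            return new, 0.0
        if kind == "root_scale":
            lo = max(state.ages[c] for c in state.children[root])
            f = math.exp(1.4 * (rng.random() - 0.5))
            new.ages[root] = lo + (state.ages[root] - lo) * f
            return new, math.log(f)
        if kind == "tree_scale":
            f = math.exp(0.5 * (rng.random() - 0.5))
            new.ages[internal] = state.ages[internal] * f
            return new, len(internal) * math.log(f)
        if kind == "subtree_scale":
            # scale every internal age inside one subtree; decorrelates deep
            # clade ages that uniform slides move only slowly
            cand = [v for v in internal if v != root]
            if not cand:
                return None
            v = int(rng.choice(cand))
            members = [v]
            stack = list(state.children[v])
            while stack:
                w = stack.pop()
                if w >= self.ntaxa:
                    members.append(w)
                stack.extend(state.children[w])
            f = math.exp(0.5 * (rng.random() - 0.5))
            new.ages[members] = state.ages[members] * f
            return new, len(members) * math.log(f)
        if kind == "up_down":
            # ridge move: all ages up, clock rate down (likelihood-preserving
            # direction of the age/rate confounding)
            f = math.exp(0.3 * (rng.random() - 0.5))
            new.ages[internal] = state.ages[internal] * f
            new.mu = state.mu / f
            return new, (len(internal) - 1) * math.log(f)
        if kind == "rate_scale":
            cand = [v for v in range(len(state.parent)) if v != root]
            v = int(rng.choice(cand))
            f = math.exp(0.8 * (rng.random() - 0.5))
            new.rates[v] = state.rates[v] * f
            return new, math.log(f)
        if kind == "mu_scale":
            f = math.exp(0.5 * (rng.random() - 0.5))
            new.mu = state.mu * f
            return new, math.log(f)
        if kind == "sigma_scale":
            if not self.clock.sample_sigma:
                return None
            f = math.exp(0.5 * (rng.random() - 0.5))
            new.sigma = state.sigma * f
            return new, math.log(f)
        if kind == "alpha_scale":
            if not self.part_names or not self.config.sample_submodel:
                return None
            name = self.part_names[int(rng.integers(len(self.part_names)))]
            f = math.exp(0.4 * (rng.random() - 0.5))
            new.alphas[name] = state.alphas[name] * f
            return new, math.log(f)
        if kind == "part_rate_scale":
            if len(self.part_names) < 2:
                return None
            name = self.part_names[1 + int(rng.integers(len(self.part_names) - 1))]
            f = math.exp(0.4 * (rng.random() - 0.5))
            new.part_rates[name] = state.part_rates[name] * f
            return new, math.log(f)
        if kind == "age_rate_slide":
            # slide one internal age while rescaling the three adjacent
            # branch rates to keep substitution lengths fixed: the
            # likelihood is invariant, so this mixes the age/rate ridge on
            # the prior alone
            cand = [v for v in internal if v != root]
            if not cand:
                return None
            v = int(rng.choice(cand))
            parent_age = state.ages[state.parent[v]]
            child_max = max(state.ages[c] for c in state.children[v])
            t_old, t_new = state.ages[v], rng.uniform(child_max, parent_age)
            log_hastings = 0.0
            d_old, d_new = parent_age - t_old, parent_age - t_new
            if d_new < 1e-9 or d_old < 1e-9:
                return None
            new.rates[v] = state.rates[v] * d_old / d_new
            log_hastings += math.log(d_old / d_new)
            for c in state.children[v]:
                d_old_c, d_new_c = t_old - state.ages[c], t_new - state.ages[c]
                if d_new_c < 1e-9 or d_old_c < 1e-9:
                    return None
                new.rates[c] = state.rates[c] * d_old_c / d_new_c
                log_hastings += math.log(d_old_c / d_new_c)
            new.ages[v] = t_new
            return new, log_hastings
        if kind == "calibration_draw":
            if not self.calibrations:
                return None
            cal = self.calibrations[int(rng.integers(len(self.calibrations)))]
            leafsets = self._leaf_sets(state.parent, state.children)
            target = [v for v, ls in leafsets.items() if ls == cal.clade]
            if not target:
                return None
            v = target[0]
            t_new = cal.sample(rng)
            new.ages[v] = t_new
            # independence proposal from the calibration density
            return new, cal.logpdf(state.ages[v]) - cal.logpdf(t_new)
        if kind == "narrow_exchange":
            cand = [v for v in internal if v != root]
            if not cand:
                return None
            v = int(rng.choice(cand))
            u = state.parent[v]
            siblings = [c for c in state.children[u] if c != v]
            a = siblings[int(rng.integers(len(siblings)))]
            w = state.children[v][int(rng.integers(len(state.children[v])))]
            if state.ages[v] <= state.ages[a]:
                return None
            # swap a (uncle) with w (child of v)
            new.children[u] = [c if c != a else w for c in new.children[u]]
            new.children[v] = [c if c != w else a for c in new.children[v]]
            new.parent[a] = v
            new.parent[w] = u
            if not self._satisfies_constraints(new):
                return None
            return new, 0.0
        raise DatingError(f"unknown proposal {kind!r}")

    # -- main loop ----------------------------------------------------------

    def run(self, tracked_clades: dict[str, frozenset] | None = None
            ) -> PosteriorSample:
        cfg = self.config
        tracked = tracked_clades or {}
        names = [k for k, w in self.weights.items() if w > 0]
        probs = np.array([self.weights[k] for k in names])
        probs = probs / probs.sum()
        chains = [self.state]
        for i in range(1, cfg.n_chains):
            chains.append(self.state.copy())
        heats = [1.0 / (1.0 + cfg.heat_delta * i) for i in range(cfg.n_chains)]
        rows = []
        tree_samples: list[dict[frozenset, float]] = []
        rng = self.rng
        for it in range(cfg.generations + 1):
            for ci, chain in enumerate(chains):
                kind = names[int(rng.choice(len(names), p=probs))]
                prop = self._propose(chain, kind)
                if prop is not None:
                    new, log_hastings = prop
                    keep = chain.ln_like if kind in self.LIKELIHOOD_INVARIANT \
                        else None
                    self._score(new, keep_likelihood=keep)
                    delta = (new.ln_like + new.ln_prior
                             - chain.ln_like - chain.ln_prior)
                    if np.isfinite(new.ln_prior) and \
                            math.log(rng.random() + 1e-300) < heats[ci] * delta + log_hastings:
                        chains[ci] = new
            if cfg.n_chains > 1 and it % 10 == 0:
                i, j = sorted(rng.choice(cfg.n_chains, 2, replace=False))
                a, b = chains[i], chains[j]
                swap = (heats[i] - heats[j]) * ((b.ln_like + b.ln_prior)
                                                - (a.ln_like + a.ln_prior))
                if math.log(rng.random() + 1e-300) < swap:
                    chains[i], chains[j] = chains[j], chains[i]
            if it % cfg.sample_interval == 0:
                cold = chains[0]
                leafsets = self._leaf_sets(cold.parent, cold.children)
                clade_ages = {leafsets[v]: float(cold.ages[v])
                              for v in range(self.ntaxa, len(cold.parent))}
                row = {"state": it, "lnL": cold.ln_like, "lnPrior": cold.ln_prior,
                       "mu": cold.mu, "sigma": cold.sigma,
                       "root_age": float(max(cold.ages))}
                for name, clade in tracked.items():
                    supersets = [c for c in clade_ages if clade <= c]
                    row[f"age_{name}"] = clade_ages[min(supersets, key=len)]
                for pname in self.part_names:
                    row[f"alpha_{pname}"] = cold.alphas[pname]
                    row[f"rate_{pname}"] = cold.part_rates[pname]
                rows.append(row)
                tree_samples.append(clade_ages)
        trace = pd.DataFrame(rows)
        burnin_idx = self._burnin_index(trace, cfg)
        return PosteriorSample(trace, tree_samples, cfg, burnin_idx)

    @staticmethod
    def _burnin_index(trace: pd.DataFrame, cfg: MCMCConfig) -> int:
        """Samples to discard: explicit burn-in, or the plateau rule.

        The plateau is the median log-posterior of the second half of the
        chain (not the maximum, which in stationarity sits several units
        above typical values); burn-in ends when the chain first reaches
        within 2 units of it, and is never less than 10% of the chain.
        """
        n = len(trace)
        if cfg.burnin is not None:
            return min(n - 1, cfg.burnin // cfg.sample_interval)
        ln_post = (trace["lnL"] + trace["lnPrior"]).to_numpy()
        plateau = float(np.median(ln_post[n // 2:]))
        above = ln_post >= plateau - 2.0
        reached = int(np.argmax(above)) if np.any(above) else 0
        return int(min(n - 1, max(n // 10, reached)))


def run_dating_mcmc(alignment: Alignment | None, scheme: PartitionScheme | None,
                    models: dict | None, clock: ClockModel,
                    tree_prior: TreePriorSpec,
                    calibrations: list[CalibrationPrior],
                    constraints: list[frozenset], config: MCMCConfig,
                    prior_only: bool = False, start: Chronogram | None = None,
                    taxa: list[str] | None = None,
                    tracked_clades: dict[str, frozenset] | None = None,
                    ) -> PosteriorSample:
    """Sample dated trees and clock parameters; see ``DatingSampler``.

    With ``prior_only`` (or ``alignment=None`` plus an explicit taxon list)
    the data term is switched off and the sampler draws from the joint prior.
    """
    cfg = MCMCConfig(**vars(config))  # copy so the caller's config is untouched
    cfg.constraints = list(cfg.constraints) + [frozenset(c) for c in constraints]
    sampler = DatingSampler(alignment, scheme, models, clock, tree_prior,
                            calibrations, cfg, prior_only=prior_only,
                            start=start, taxa=taxa)
    return sampler.run(tracked_clades)


# ---------------------------------------------------------------------------
# Trace diagnostics and summaries
# ---------------------------------------------------------------------------

def ess(trace: np.ndarray) -> tuple[float, bool]:
    """Effective sample size, n / (1 + 2 * sum of autocorrelations).

    The autocorrelation sum is truncated at the first non-positive adjacent
    pair (Geyer's initial positive sequence). Returns (ess, zero_variance);
    a constant trace reports ESS = n with the flag set.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 10:
        raise DatingError("trace too short for ESS")
    if np.allclose(x, x[0]):
        return float(n), True
    nlags = min(n - 2, 1000)
    rho = acf(x, nlags=nlags, fft=True)[1:]
    total = 0.0
    k = 0
    while k + 1 < len(rho):
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        total += pair
        k += 2
    else:
        if k < len(rho) and rho[k] > 0:
            total += rho[k]
    return float(n / (1.0 + 2.0 * total)), False


def ess_table(trace: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col in trace.columns:
        if col == "state":
            continue
        val, flag = ess(trace[col].to_numpy())
        rows.append({"parameter": col, "ess": val, "zero_variance": flag})
    return pd.DataFrame(rows)


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * n) sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise DatingError("need at least 20 samples for an HPD interval")
    if not 0.0 < mass <= 1.0:
        raise DatingError("mass must be in (0, 1]")
    k = int(math.ceil(mass * n))
    widths = x[k - 1:] - x[:n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def mcc_tree(tree_samples: list[dict[frozenset, float]] | PosteriorSample,
             burnin: int = 0) -> Chronogram:
    """Maximum clade credibility tree with median node heights and 95% HPDs.

    The topology maximizes the product of posterior clade probabilities among
    *sampled* topologies; each node's age is the median of that clade's
    sampled ages (child ages are capped at the parent's to keep the summary
    tree ultrametric when medians of rarely co-sampled clades cross).
    """
    if isinstance(tree_samples, PosteriorSample):
        _, samples = tree_samples.post_burnin()
    else:
        samples = tree_samples[burnin:]
    if not samples:
        raise DatingError("no post-burnin tree samples")
    nsamp = len(samples)
    clade_counts: dict[frozenset, int] = {}
    clade_ages: dict[frozenset, list[float]] = {}
    topo_counts: dict[frozenset, int] = {}
    topo_example: dict[frozenset, dict[frozenset, float]] = {}
    for sample in samples:
        key = frozenset(sample.keys())
        topo_counts[key] = topo_counts.get(key, 0) + 1
        topo_example.setdefault(key, sample)
        for clade, age in sample.items():
            clade_counts[clade] = clade_counts.get(clade, 0) + 1
            clade_ages.setdefault(clade, []).append(age)
    best_topo = max(topo_counts,
                    key=lambda k: sum(math.log(clade_counts[c] / nsamp) for c in k))
    taxa = sorted(frozenset().union(*best_topo))
    joins = []
    support = {}
    hpds = {}
    med = {c: float(np.median(clade_ages[c])) for c in best_topo}
    for clade in sorted(best_topo, key=len):
        parents = [c for c in best_topo if clade < c]
        age = med[clade]
        if parents:
            age = min(age, med[min(parents, key=len)])
        med[clade] = age
        joins.append((clade, age))
        support[clade] = clade_counts[clade] / nsamp
        if len(clade_ages[clade]) >= 20:
            hpds[clade] = hpd_interval(clade_ages[clade])
    chron = build_chronogram(joins, taxa)
    chron.hpd = hpds
    chron.clade_support = support
    return chron


def scale_relative_node_age(depth_fraction: float, reference_age: float,
                            reference_ci: tuple[float, float]
                            ) -> tuple[float, tuple[float, float]]:
    """Age of an undated node as a fraction of the depth of its closest dated
    ancestor: pointwise scaling of the reference age and interval."""
    if not 0.0 < depth_fraction <= 1.0:
        raise DatingError("depth fraction must be in (0, 1]")
    if reference_age <= 0:
        raise DatingError("reference age must be positive")
    lo, hi = reference_ci
    return (depth_fraction * reference_age,
            (depth_fraction * lo, depth_fraction * hi))
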