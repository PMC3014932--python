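"""Substitution models: GTR and two-state (RY) time-reversible models with
invariant sites and discrete-gamma rate heterogeneity.

Rate matrices are scaled so that one unit of branch length equals one expected
substitution per site at stationarity. Transition probabilities come from the
symmetric eigendecomposition available for any reversible model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

NUC_STATES = "ACGT"
RY_STATES = "RY"
#: order of the six GTR exchangeability parameters
GTR_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT


class ModelError(ValueError):
    pass


@dataclass
class GTRModel:
    """General time-reversible nucleotide model, +I +Gamma(n_cat).

    ``exchangeabilities`` in order AC, AG, AT, CG, CT, GT with GT conventionally
    fixed to 1; ``base_freqs`` over A, C, G, T.
    """

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))
    base_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    p_inv: float = 0.0
    alpha: float = np.inf
    n_cat: int = 4

    nstates: int = 4
    states: str = NUC_STATES

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities < 0):
            raise ModelError("need 6 non-negative exchangeabilities")
        _validate_common(self)

    def copy(self) -> "GTRModel":
        return GTRModel(self.exchangeabilities.copy(), self.base_freqs.copy(),
                        self.p_inv, self.alpha, self.n_cat)


@dataclass
class BinaryModel:
    """Two-state reversible model for RY-recoded characters, +I +Gamma(n_cat).

    The binary analogue of the frequency-parameterized models applied to
    purine/pyrimidine data; state frequencies are free parameters.
    """

    state_freqs: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))
    p_inv: float = 0.0
    alpha: float = np.inf
    n_cat: int = 4

    nstates: int = 2
    states: str = RY_STATES

    def __post_init__(self) -> None:
        self.state_freqs = np.asarray(self.state_freqs, dtype=float)
        _validate_common(self)

    @property
    def base_freqs(self) -> np.ndarray:
        return self.state_freqs

    def copy(self) -> "BinaryModel":
        return BinaryModel(self.state_freqs.copy(), self.p_inv, self.alpha, self.n_cat)


def _validate_common(model) -> None:
    freqs = model.base_freqs
    if freqs.shape != (model.nstates,) or np.any(freqs <= 0):
        raise ModelError("state frequencies must be positive")
    if abs(freqs.sum() - 1.0) > 1e-8:
        raise ModelError("state frequencies must sum to 1")
    if not 0.0 <= model.p_inv < 1.0:
        raise ModelError("p_inv must lie in [0, 1)")
    if not model.alpha > 0:
        raise ModelError("alpha must be positive")
    if model.n_cat < 1:
        raise ModelError("n_cat must be >= 1")


def build_rate_matrix(model) -> np.ndarray:
    """Normalized instantaneous rate matrix Q.

    Rows sum to zero and -sum_i pi_i Q_ii = 1, so branch lengths are expected
    substitutions per site.
    """
    freqs = model.base_freqs
    n = model.nstates
    Q = np.zeros((n, n))
    if n == 4:
        for rate, (i, j) in zip(model.exchangeabilities, GTR_PAIRS):
            if rate > 0 and (freqs[i] == 0 or freqs[j] == 0):
                raise ModelError("zero frequency on a nonzero exchangeability path")
            Q[i, j] = rate * freqs[j]
            Q[j, i] = rate * freqs[i]
    else:
        Q[0, 1] = freqs[1]
        Q[1, 0] = freqs[0]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(freqs, np.diag(Q))
    if scale <= 0:
        raise ModelError("degenerate rate matrix")
    return Q / scale


@dataclass
class EigenSystem:
    """Symmetric eigendecomposition of a reversible Q; P(t) = U exp(L t) V."""

    evals: np.ndarray
    U: np.ndarray
    V: np.ndarray

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """P(t) for an arbitrary-shaped array of branch lengths.

        Returns an array of shape ``lengths.shape + (n, n)``.
        """
        lengths = np.asarray(lengths, dtype=float)
        expo = np.exp(np.multiply.outer(lengths, self.evals))
        P = np.einsum("ij,...j,jk->...ik", self.U, expo, self.V)
        return np.clip(P, 0.0, None)


def eigensystem(model) -> EigenSystem:
    Q = build_rate_matrix(model)
    pi = model.base_freqs
    sqrt_pi = np.sqrt(pi)
    S = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
    S = (S + S.T) / 2.0  # enforce exact symmetry
    evals, W = np.linalg.eigh(S)
    U = W / sqrt_pi[:, None]
    V = W.T * sqrt_pi[None, :]
    return EigenSystem(evals, U, V)


def discretize_gamma(alpha: float, n_cat: int, method: str = "mean") -> tuple[np.ndarray, np.ndarray]:
    """Discrete-gamma category rates and weights (mean 1, equal weights).

    ``method="mean"`` uses the mean rate of each equal-probability bin (the
    default behind "+G4" in the standard likelihood programs); ``"median"``
    uses bin medians rescaled to mean 1.
    """
    if not alpha > 0:
        raise ModelError("alpha must be positive")
    if n_cat < 1:
        raise ModelError("n_cat must be >= 1")
    if n_cat == 1 or not np.isfinite(alpha):
        return np.ones(n_cat), np.full(n_cat, 1.0 / n_cat)
    weights = np.full(n_cat, 1.0 / n_cat)
    probs = np.arange(1, n_cat) / n_cat
    # quantile boundaries of Gamma(shape=alpha, rate=alpha)
    bounds = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    if method == "median":
        mids = (np.arange(n_cat) + 0.5) / n_cat
        rates = gamma_dist.ppf(mids, a=alpha, scale=1.0 / alpha)
        rates = rates / np.dot(rates, weights)
        return rates, weights
    if method != "mean":
        raise ModelError(f"unknown discretization method {method!r}")
    # mean within each bin: n_cat * [I(alpha+1, a*b_hi) - I(alpha+1, a*b_lo)]
    cum = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * bounds), [1.0]])
    rates = n_cat * np.diff(cum)
    rates = rates / np.dot(rates, weights)  # exact mean-1 normalization
    return rates, weights


def rate_mixture(model, method: str = "mean") -> tuple[np.ndarray, np.ndarray]:
    """Category rates/weights of the full +I+Gamma mixture.

    The invariant class (rate 0, weight p_inv) is prepended; the gamma classes
    share the remaining 1 - p_inv weight equally.
    """
    g_rates, g_weights = discretize_gamma(model.alpha, model.n_cat, method)
    rates = np.concatenate([[0.0], g_rates])
    weights = np.concatenate([[model.p_inv], (1.0 - model.p_inv) * g_weights])
    return rates, weights


def encode_leaf_partials(states: str, column: str) -> np.ndarray:
    """Partial-likelihood row for one observed character (ambiguity-aware)."""
    from .alignments import IUPAC

    vec = np.zeros(len(states))
    if states == RY_STATES:
        compat = {"R": "R", "Y": "Y", "?": "RY", "-": "RY", "N": "RY"}.get(column, "RY")
        for i, s in enumerate(states):
            vec[i] = 1.0 if s in compat else 0.0
    else:
        compat = IUPAC.get(column, "ACGT")
        for i, s in enumerate(states):
            vec[i] = 1.0 if s in compat else 0.0
    return vec
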