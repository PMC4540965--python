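"""Two-site binary coevolution model.

A pair of binary characters evolves as a continuous-time Markov chain on the
joint state space ``(00, 01, 10, 11)``.  Without selection each site mutates
independently (only single changes have nonzero instantaneous rate).  With
coevolutionary selection of strength ``S`` the matched states 00/11 are
favored and the mismatched states 01/10 are equally deleterious: every
mutational rate is scaled by the fixation factor ``S / (1 - exp(-S))`` for
transitions into a favored state and by the same factor evaluated at ``-S``
for transitions into a deleterious state.  ``S`` is the population-scaled
selection coefficient (2*Ne*s for haploids); the mutation rate is absorbed
into the time scale, so ``t`` is measured in expected substitutions of the
neutral pair process.

The module provides the generator constructors, the stationary distribution,
the relative substitution rate of the coevolving versus the independent
process, and the stationary probabilities of observing no, single, or double
differences across a time interval ``t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "STATES",
    "SINGLE_CHANGE_PAIRS",
    "DOUBLE_CHANGE_PAIRS",
    "PairModelParams",
    "ChangeClassProbs",
    "fixation_factor",
    "build_qmut",
    "build_qcoevo",
    "stationary_distribution",
    "relative_rate",
    "transition_probabilities",
    "change_class_probs",
    "single_fraction",
]

#: Fixed ordering of the joint states of the site pair.
STATES = ("00", "01", "10", "11")

#: Ordered index pairs differing at exactly one site.
SINGLE_CHANGE_PAIRS = tuple(
    (i, j)
    for i in range(4)
    for j in range(4)
    if i != j and sum(a != b for a, b in zip(STATES[i], STATES[j])) == 1
)

#: Ordered index pairs differing at both sites (00<->11, 01<->10).
DOUBLE_CHANGE_PAIRS = tuple(
    (i, j)
    for i in range(4)
    for j in range(4)
    if sum(a != b for a, b in zip(STATES[i], STATES[j])) == 2
)

_FAVORED = (0, 3)  # 00 and 11


class InvalidParameterError(ValueError):
    """Raised for parameter values outside the model's domain."""


@dataclass(frozen=True)
class PairModelParams:
    """Parameters of the two-site coevolution process.

    Parameters
    ----------
    S
        Population-scaled selection coefficient.  ``S = 0`` is the
        independent process; positive values favor the matched states.
    t
        Elapsed time in expected substitutions of the neutral pair process.
    pi0, pi1
        Mutational equilibrium frequencies of states 0 and 1 at a single
        site.  They must sum to 1.
    """

    S: float = 0.0
    t: float = 1.0
    pi0: float = 0.5
    pi1: float = 0.5

    def __post_init__(self) -> None:
        if not math.isfinite(self.S):
            raise InvalidParameterError(f"S must be finite, got {self.S}")
        if self.t < 0:
            raise InvalidParameterError(f"t must be >= 0, got {self.t}")
        _check_frequencies(self.pi0, self.pi1)


@dataclass(frozen=True)
class ChangeClassProbs:
    """Stationary probabilities of observing no/single/double differences."""

    p_none: float
    p_single: float
    p_double: float

    def __post_init__(self) -> None:
        total = self.p_none + self.p_single + self.p_double
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"change-class probabilities sum to {total}, not 1")


def _check_frequencies(pi0: float, pi1: float, tol: float = 1e-9) -> None:
    if not (math.isfinite(pi0) and math.isfinite(pi1)):
        raise InvalidParameterError("state frequencies must be finite")
    if pi0 < 0 or pi1 < 0 or abs(pi0 + pi1 - 1.0) > tol:
        raise InvalidParameterError(
            f"state frequencies must be non-negative and sum to 1, got {pi0}, {pi1}"
        )


def fixation_factor(S: float) -> float:
    """Selection-dependent scaling ``S / (1 - exp(-S))`` of a mutation's rate.

    This is the classic diffusion-theory fixation probability of a new
    mutation in a haploid population, relative to a neutral one.  The S -> 0
    limit is 1 (the function is continuously extended with a series expansion
    near zero); the function is positive and strictly increasing in ``S``.
    """
    if not math.isfinite(S):
        raise InvalidParameterError(f"S must be finite, got {S}")
    if abs(S) < 1e-6:
        # S/(1-e^-S) = 1 + S/2 + S^2/12 + O(S^4)
        return 1.0 + S / 2.0 + S * S / 12.0
    return S / -math.expm1(-S)


def build_qmut(pi0: float = 0.5, pi1: float = 0.5) -> np.ndarray:
    """Generator of two independent binary sites over (00, 01, 10, 11).

    Each single-site change occurs at the mutational rate toward the target
    state's frequency; the instantaneous rate of double changes (e.g.
    00 -> 11) is exactly zero.
    """
    _check_frequencies(pi0, pi1)
    rate_to = {"0": pi0, "1": pi1}
    q = np.zeros((4, 4))
    for i, j in SINGLE_CHANGE_PAIRS:
        # the symbol that changes determines the target-frequency rate
        changed = next(k for k in (0, 1) if STATES[i][k] != STATES[j][k])
        q[i, j] = rate_to[STATES[j][changed]]
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def build_qcoevo(params: PairModelParams) -> np.ndarray:
    """Generator of the coevolving pair process.

    Every allowed mutational rate from :func:`build_qmut` is multiplied by
    ``fixation_factor(+S)`` when the target state is favored (00 or 11) and
    by ``fixation_factor(-S)`` when it is deleterious (01 or 10).  ``S = 0``
    recovers the independent generator exactly.
    """
    qmut = build_qmut(params.pi0, params.pi1)
    f_plus = fixation_factor(params.S)
    f_minus = fixation_factor(-params.S)
    q = np.zeros((4, 4))
    for i, j in SINGLE_CHANGE_PAIRS:
        q[i, j] = qmut[i, j] * (f_plus if j in _FAVORED else f_minus)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_distribution(params: PairModelParams) -> np.ndarray:
    """Stationary distribution of the coevolving pair process.

    The unnormalized weights are the mutational joint frequencies times the
    fixation factor of the state's selective class:
    ``pi_00 = c * pi0^2 * f(S)``, ``pi_01 = pi_10 = c * pi0*pi1 * f(-S)``,
    ``pi_11 = c * pi1^2 * f(S)``, with ``c`` normalizing the sum to 1.
    """
    p0, p1, S = params.pi0, params.pi1, params.S
    w = np.array(
        [
            p0 * p0 * fixation_factor(S),
            p0 * p1 * fixation_factor(-S),
            p1 * p0 * fixation_factor(-S),
            p1 * p1 * fixation_factor(S),
        ]
    )
    return w / w.sum()


def relative_rate(S: float, pi0: float = 0.5, pi1: float = 0.5) -> float:
    """Total substitution rate of the coevolving process relative to the
    independent process, each evaluated at its own stationary distribution.

    Computed directly as ``(-sum_i pi_i Q_ii) / (-sum_i pi^mut_i Q^mut_ii)``.
    Equals 1 at ``S = 0``; for ``pi0 = pi1 = 1/2`` it has the closed form
    ``2 S exp(-S) / (1 - exp(-2S))``.
    """
    params = PairModelParams(S=S, pi0=pi0, pi1=pi1)
    q = build_qcoevo(params)
    pi = stationary_distribution(params)
    qmut = build_qmut(pi0, pi1)
    pimut = np.array([pi0 * pi0, pi0 * pi1, pi1 * pi0, pi1 * pi1])
    rate = -float(pi @ np.diag(q))
    rate_mut = -float(pimut @ np.diag(qmut))
    return rate / rate_mut


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition probability matrix ``P(t) = exp(Q t)``.

    For reversible generators (all generators in this model are reversible)
    P(t) is computed by eigendecomposition of the pi^(1/2)-symmetrized
    generator, which is exact and stable for stiff Q at large ``S``; if the
    symmetrization is not applicable the scaling-and-squaring exponential is
    used.
    """
    Q = np.asarray(Q, dtype=float)
    if t < 0:
        raise InvalidParameterError(f"t must be >= 0, got {t}")
    if Q.shape[0] != Q.shape[1]:
        raise InvalidParameterError("Q must be square")
    if t == 0:
        return np.eye(Q.shape[0])
    pi = _left_null_distribution(Q)
    if pi is not None and np.all(pi > 1e-300):
        d = np.sqrt(pi)
        sym = (d[:, None] * Q) / d[None, :]
        if np.allclose(sym, sym.T, atol=1e-10):
            evals, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
            core = (vecs * np.exp(evals * t)) @ vecs.T
            p = core / d[:, None] * d[None, :]
            p = np.clip(p, 0.0, 1.0)
            return p / p.sum(axis=1, keepdims=True)
    return expm(Q * t)


def _left_null_distribution(Q: np.ndarray) -> np.ndarray | None:
    """Stationary distribution of a generator, or None if not well defined."""
    evals, vecs = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(evals)))
    if abs(evals[k]) > 1e-8:
        return None
    v = np.real(vecs[:, k])
    if v.sum() == 0:
        return None
    v = v / v.sum()
    if np.any(v < -1e-12):
        return None
    return np.clip(v, 0.0, None)


def change_class_probs(params: PairModelParams) -> ChangeClassProbs:
    """Stationary probabilities of observing no, single, or double change
    across an interval of length ``params.t``.

    The start state is drawn from the coevolutionary stationary distribution;
    the classes compare the states at the two ends of the interval, so a
    "double change" means the endpoints differ at both sites (the path must
    have passed through an intermediate, as instantaneous double changes are
    forbidden).
    """
    q = build_qcoevo(params)
    pi = stationary_distribution(params)
    p = transition_probabilities(q, params.t)
    p_single = float(sum(pi[i] * p[i, j] for i, j in SINGLE_CHANGE_PAIRS))
    p_double = float(sum(pi[i] * p[i, j] for i, j in DOUBLE_CHANGE_PAIRS))
    p_none = float(sum(pi[i] * p[i, i] for i in range(4)))
    # guard against rounding drift before the dataclass invariant check
    total = p_none + p_single + p_double
    return ChangeClassProbs(p_none / total, p_single / total, p_double / total)


def single_fraction(params: PairModelParams) -> float:
    """Fraction of observable change events that are single (one-site).

    ``p_single / (p_single + p_double)``; undefined at ``t = 0`` where no
    changes can be observed.
    """
    if params.t == 0:
        raise InvalidParameterError("single_fraction is undefined at t = 0")
    probs = change_class_probs(params)
    denom = probs.p_single + probs.p_double
    if denom <= 0:
        raise InvalidParameterError("no observable changes: p_single + p_double = 0")
    return probs.p_single / denom
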