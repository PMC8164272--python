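"""Continuous-time Markov substitution models.

Everything downstream (the novelty-score recursions, the oracles, the
simulators) consumes two quantities per branch of length ``t``:

* the transition-probability matrix ``P_t = expm(t * Q)``, and
* the per-state no-substitution probabilities ``I_t[j] = exp(t * Q[j, j])``,
  i.e. the probability that *zero* events occur on the branch given start
  state ``j``.  ``I_t[j] <= P_t[j, j]`` always: identity by state does not
  imply identity by descent.

Models are normalised at construction so that the expected substitution
rate at equilibrium is one event per unit branch length
(``-sum_j pi[j] * Q[j, j] == 1``), matching branch lengths expressed in
expected substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from ._lg_data import LG_EXCHANGEABILITIES, LG_FREQUENCIES, LG_STATES

NUCLEOTIDES = ("A", "C", "G", "T")
AMINO_ACIDS = tuple(LG_STATES)

#: purine/pyrimidine pairs whose interchanges are transitions under HKY85
_TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class InvalidModelError(ValueError):
    """Raised for non-stochastic frequencies, bad kappa, malformed Q, ..."""


@dataclass
class RateModel:
    """A stationary substitution model: state space, rate matrix, equilibrium.

    Parameters
    ----------
    states:
        Ordered character symbols; alphabet size ``B = len(states)``.
    Q:
        ``B x B`` rate matrix, rows summing to zero, off-diagonals >= 0,
        in units of substitutions per unit branch length.
    pi:
        Equilibrium distribution (stationary for ``Q``).
    name:
        Identifier: ``JC69 | HKY85 | LG | custom``.
    kappa:
        Transition:transversion rate ratio, recorded for HKY85 only.
    """

    states: tuple[str, ...]
    Q: np.ndarray
    pi: np.ndarray
    name: str = "custom"
    kappa: float | None = None
    _decomp: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.Q = np.asarray(self.Q, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        B = len(self.states)
        if self.Q.shape != (B, B):
            raise InvalidModelError(
                f"Q has shape {self.Q.shape}, expected ({B}, {B})"
            )
        if self.pi.shape != (B,) or np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise InvalidModelError("pi must be a probability distribution over the states")
        off = self.Q[~np.eye(B, dtype=bool)]
        if np.any(off < -1e-15):
            raise InvalidModelError("off-diagonal rates must be non-negative")
        scale = max(1.0, float(np.max(np.abs(self.Q))))
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-12 * scale:
            raise InvalidModelError("rows of Q must sum to 0")
        if np.max(np.abs(self.pi @ self.Q)) > 1e-10 * scale:
            raise InvalidModelError("pi is not stationary for Q (pi @ Q != 0)")

    # -- basic descriptors -------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, symbol: str) -> int:
        return self.states.index(symbol)

    @property
    def is_reversible(self) -> bool:
        flux = self.pi[:, None] * self.Q
        return bool(np.max(np.abs(flux - flux.T)) < 1e-10)

    # -- transition probabilities ------------------------------------------

    def _eigensystem(self):
        """Cached spectral decomposition of the pi^{1/2}-symmetrised Q.

        For a reversible model, ``S = D Q D^-1`` with ``D = diag(sqrt(pi))``
        is symmetric, so ``P_t = D^-1 V exp(L t) V' D`` with an orthogonal V.
        Exact (to machine precision) and one decomposition per model.
        """
        if self._decomp is None:
            sqrt_pi = np.sqrt(self.pi)
            S = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
            lam, V = np.linalg.eigh((S + S.T) / 2.0)
            self._decomp = (lam, (V / sqrt_pi[:, None]), (V.T * sqrt_pi[None, :]))
        return self._decomp

    def transition_matrix(self, t: float) -> np.ndarray:
        """``P_t = expm(t Q)``; rows sum to 1."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        if self.is_reversible:
            lam, left, right = self._eigensystem()
            P = (left * np.exp(lam * t)) @ right
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=1, keepdims=True)
            return P
        return expm(t * self.Q)

    def no_substitution_probabilities(self, t: float) -> np.ndarray:
        """``I_t[j] = exp(t * Q[j, j])``, probability of zero events."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        return np.exp(t * np.diag(self.Q))


@dataclass(frozen=True)
class BranchKernel:
    """Transition matrix and no-substitution vector for one branch."""

    P: np.ndarray
    I: np.ndarray
    t: float


def branch_kernel(model: RateModel, t: float) -> BranchKernel:
    """Precompute ``P_t`` and ``I_t`` for a branch of length ``t >= 0``."""
    return BranchKernel(
        P=model.transition_matrix(t),
        I=model.no_substitution_probabilities(t),
        t=float(t),
    )


# -- constructors ----------------------------------------------------------


def _normalise_rate(Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    rate = -float(pi @ np.diag(Q))
    if rate <= 0:
        raise InvalidModelError("expected substitution rate at equilibrium is not positive")
    return Q / rate


def jc69() -> RateModel:
    """Jukes-Cantor 1969: all substitution rates 1/3, uniform equilibrium."""
    B = 4
    Q = np.full((B, B), 1.0 / 3.0)
    np.fill_diagonal(Q, -1.0)
    return RateModel(NUCLEOTIDES, Q, np.full(B, 0.25), name="JC69")


def hky85(kappa: float = 3.0, pi=(0.25, 0.25, 0.25, 0.25)) -> RateModel:
    """HKY85: kappa multiplies transition (A<->G, C<->T) rates.

    Normalised to one expected substitution per unit branch length.
    """
    if kappa < 0:
        raise InvalidModelError(f"kappa must be non-negative, got {kappa}")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise InvalidModelError("HKY85 requires a length-4 probability vector pi")
    pi = pi / pi.sum()
    Q = np.zeros((4, 4))
    for a, sa in enumerate(NUCLEOTIDES):
        for b, sb in enumerate(NUCLEOTIDES):
            if a == b:
                continue
            Q[a, b] = pi[b] * (kappa if (sa, sb) in _TRANSITION_PAIRS else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateModel(NUCLEOTIDES, _normalise_rate(Q, pi), pi, name="HKY85", kappa=float(kappa))


def _parse_lg_tables():
    B = 20
    S = np.zeros((B, B))
    for i, line in enumerate(LG_EXCHANGEABILITIES.strip().splitlines(), start=1):
        vals = [float(v) for v in line.split()]
        S[i, : len(vals)] = vals
    S = S + S.T
    pi = np.array([float(v) for v in LG_FREQUENCIES.split()])
    return S, pi / pi.sum()


def lg(pi=None) -> RateModel:
    """Le-Gascuel 2008 amino-acid model; optionally with replaced frequencies."""
    S, pi_lg = _parse_lg_tables()
    freqs = pi_lg if pi is None else np.asarray(pi, dtype=float)
    if freqs.shape != (20,) or np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-8:
        raise InvalidModelError("LG requires a length-20 probability vector pi")
    freqs = freqs / freqs.sum()
    Q = S * freqs[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateModel(AMINO_ACIDS, _normalise_rate(Q, freqs), freqs, name="LG")


def custom_model(
    states,
    Q=None,
    exchangeabilities=None,
    pi=None,
    normalise: bool = True,
) -> RateModel:
    """Arbitrary model from a raw rate matrix or exchangeabilities + pi.

    With ``exchangeabilities`` (symmetric ``S``), builds the reversible
    ``Q[j, k] = S[j, k] * pi[k]``.  With a raw ``Q``, ``pi`` defaults to the
    stationary distribution (left null vector).  ``normalise=False`` keeps
    the supplied rates untouched.
    """
    states = tuple(states)
    B = len(states)
    if (Q is None) == (exchangeabilities is None):
        raise InvalidModelError("supply exactly one of Q or exchangeabilities")
    if exchangeabilities is not None:
        S = np.asarray(exchangeabilities, dtype=float)
        if S.shape != (B, B):
            raise InvalidModelError(f"exchangeability matrix has shape {S.shape}, expected ({B}, {B})")
        if pi is None:
            raise InvalidModelError("exchangeabilities require pi")
        pi = np.asarray(pi, dtype=float)
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
    else:
        Q = np.asarray(Q, dtype=float)
        if Q.shape != (B, B):
            raise InvalidModelError(f"Q has shape {Q.shape}, expected ({B}, {B})")
        if pi is None:
            # stationary distribution: left null vector of Q
            lam, vec = np.linalg.eig(Q.T)
            k = int(np.argmin(np.abs(lam)))
            pi = np.real(vec[:, k])
            pi = np.abs(pi) / np.abs(pi).sum()
        else:
            pi = np.asarray(pi, dtype=float)
    if normalise:
        Q = _normalise_rate(Q, pi)
    return RateModel(states, Q, pi, name="custom")


def make_model(name: str, **params) -> RateModel:
    """Dispatch on a model identifier: ``JC69 | HKY85 | LG | custom``."""
    key = name.upper()
    if key == "JC69":
        return jc69()
    if key == "HKY85":
        return hky85(params.get("kappa", 3.0), params.get("pi", (0.25,) * 4))
    if key == "LG":
        return lg(params.get("pi"))
    if key == "CUSTOM":
        return custom_model(**params)
    raise InvalidModelError(f"unknown model {name!r}")
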