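"""Per-column character-frequency inference from sequence weights.

Point estimate: the weighted observed frequency
``p^w(j) = sum_s w_s d(j, D_s) / sum_s w_s`` (missing rows drop out of
both sums).  Bayesian variant: approximating the column likelihood as
``prod_s pi(D_s)^{w_s}`` and taking a uniform prior makes the posterior a
Dirichlet with ``alpha_j = 1 + sum_s w_s d(j, D_s)``, whose mean is the
weighted frequency with one pseudo-count per character, whose marginals
are Beta, and whose mode recovers ``p^w`` exactly.  A conservation score
in bits (``log2 B`` minus the column entropy) completes the sequence-logo
toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

from .alignment import MISSING, AlignmentColumn
from .pns import WeightSet


class UndefinedEstimateError(ValueError):
    """No usable observations (all rows missing, or zero total weight)."""


@dataclass(frozen=True)
class FrequencyEstimate:
    """A point estimate of the column's equilibrium character frequencies."""

    freqs: np.ndarray
    states: tuple[str, ...]
    method: str
    column: int | None = None

    def __getitem__(self, state: str) -> float:
        return float(self.freqs[self.states.index(state)])


@dataclass(frozen=True)
class DirichletPosterior:
    """Dirichlet posterior over column frequencies (uniform prior + weights)."""

    alpha: np.ndarray
    states: tuple[str, ...]

    @property
    def alpha0(self) -> float:
        return float(self.alpha.sum())

    @property
    def B(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class ConservationScore:
    """Sequence-logo stack height: ``R = S_max - S_obs`` in bits."""

    R: float
    S_max: float
    S_obs: float


def _weight_and_counts(column: AlignmentColumn, weights: WeightSet | None):
    B = len(column.states)
    wsum = np.zeros(B)
    total = 0.0
    for lab, code in zip(column.labels, column.codes):
        if code == MISSING:
            continue
        w = 1.0 if weights is None else weights.weights[lab]
        wsum[code] += w
        total += w
    return wsum, total


def observed_frequencies(column: AlignmentColumn) -> FrequencyEstimate:
    """Relative character counts over the non-missing rows."""
    wsum, total = _weight_and_counts(column, None)
    if total <= 0:
        raise UndefinedEstimateError("all rows missing: observed frequencies undefined")
    return FrequencyEstimate(wsum / total, column.states, "counts", column.index)


def weighted_frequencies(column: AlignmentColumn, weights: WeightSet) -> FrequencyEstimate:
    """Weighted observed frequencies ``p^w(j)`` under any weighting scheme."""
    wsum, total = _weight_and_counts(column, weights)
    if total <= 0:
        raise UndefinedEstimateError("zero total weight over the observed rows")
    return FrequencyEstimate(
        wsum / total, column.states, f"weighted:{weights.scheme}", column.index
    )


def dirichlet_posterior(
    column: AlignmentColumn, weights: WeightSet | None = None
) -> DirichletPosterior:
    """``alpha_j = 1 + sum_s w_s d(j, D_s)``; all-missing gives the pure prior."""
    wsum, _ = _weight_and_counts(column, weights)
    return DirichletPosterior(1.0 + wsum, column.states)


def posterior_mean(post: DirichletPosterior) -> FrequencyEstimate:
    """``alpha_j / alpha_0``: weighted frequencies with one pseudo-count each."""
    return FrequencyEstimate(post.alpha / post.alpha0, post.states, "bayes:mean")


def posterior_variance(post: DirichletPosterior) -> np.ndarray:
    """Per-state posterior variance ``a_j (a_0 - a_j) / (a_0^2 (a_0 + 1))``."""
    a0 = post.alpha0
    return post.alpha * (a0 - post.alpha) / (a0**2 * (a0 + 1.0))


def credible_interval(
    post: DirichletPosterior, state: str, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tail interval from the Beta(alpha_j, alpha_0 - alpha_j) marginal."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    j = post.states.index(state)
    a = float(post.alpha[j])
    b = post.alpha0 - a
    if b <= 0:
        raise ValueError("degenerate marginal: alpha_0 == alpha_j")
    tail = (1.0 - level) / 2.0
    return (
        float(beta_dist.ppf(tail, a, b)),
        float(beta_dist.ppf(1.0 - tail, a, b)),
    )


def conservation_score(freqs: FrequencyEstimate) -> ConservationScore:
    """Information content in bits; ``0 * log2(0)`` is taken as 0."""
    p = freqs.freqs
    B = len(freqs.states)
    nz = p[p > 0]
    s_obs = float(-(nz * np.log2(nz)).sum())
    s_max = float(np.log2(B))
    return ConservationScore(R=s_max - s_obs, S_max=s_max, S_obs=s_obs)
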