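"""Phylogenetic novelty scores via exact up-down pruning.

The novelty score of a tip ``s`` is ``w_s = E[1 / i(s)]``, the expected
reciprocal of the number of tips (including ``s`` itself) whose characters
are *phylogenetically identical by descent* (PIBD) to ``s`` at a generic
alignment column: descended from a common ancestral character with zero
substitution events on the connecting path.  The conditional variant
``w_s^D`` conditions the PIBD-class-size distribution on an observed
column ``D``.  The effective sequence number (ESN) is the weight total
``T = sum_s w_s``, the expected number of evolutionarily distinct
character observations at a column.

The algorithm is a two-pass adaptation of Felsenstein pruning.  Messages
carry a joint distribution over (PIBD count ``i``, state ``j``): a
post-order "up" phase propagates, for each node, the probability of the
subtree data together with the number of subtree tips still connected to
the node by substitution-free paths; a pre-order "down" phase does the
same for the complement of each subtree; the two meet at every tip.
Total cost is O(N^3) in the tip count (the convolution that merges two
child messages is the quadratic step).

Marginalising the PIBD count in any up message recovers the ordinary
partial likelihood, so the normaliser of the conditional distributions
equals the column's phylogenetic likelihood -- a cross-check used in the
test suite against an independently coded pruning likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import MISSING, AlignmentColumn
from .models import RateModel, branch_kernel
from .tree import RootedPhylogeny


class ImpossibleDataError(ValueError):
    """The observed column has zero likelihood under the model."""


@dataclass
class PibdDistribution:
    """Distribution of a tip's PIBD-class size, optionally given a column.

    ``p[i]`` is the probability that exactly ``i`` tips (including this
    one) are PIBD to this tip; ``p[0] = 0`` and the entries sum to 1.
    """

    label: str
    p: np.ndarray
    conditional: bool = False

    @property
    def weight(self) -> float:
        """``sum_i p[i] / i``: the (conditional) novelty score."""
        i = np.arange(1, len(self.p))
        return float(np.sum(self.p[1:] / i))

    @property
    def expected_class_size(self) -> float:
        i = np.arange(len(self.p))
        return float(np.sum(i * self.p))


@dataclass
class WeightSet:
    """Named per-tip weights under one scheme, with the ESN total."""

    scheme: str
    weights: dict[str, float]
    column: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def esn(self) -> float:
        """Total weight ``T = sum_s w_s`` (the effective sequence number)."""
        return float(sum(self.weights.values()))

    def normalized(self) -> dict[str, float]:
        """Sum-to-1 view, for cross-scheme comparison."""
        total = self.esn
        if total <= 0:
            raise ValueError("cannot normalise an all-zero weight set")
        return {s: w / total for s, w in self.weights.items()}

    def as_array(self, labels) -> np.ndarray:
        return np.array([self.weights[lab] for lab in labels])

    def __getitem__(self, label: str) -> float:
        return self.weights[label]


@dataclass
class PibdResult:
    """Per-tip PIBD distributions plus the column likelihood ``P(D)``."""

    distributions: list[PibdDistribution]
    likelihood: float
    conditional: bool

    def weight_set(self, scheme: str, column_index=None, metadata=None) -> WeightSet:
        return WeightSet(
            scheme=scheme,
            weights={d.label: d.weight for d in self.distributions},
            column=column_index,
            metadata=metadata or {},
        )


# -- message helpers -------------------------------------------------------


def _tip_like(model: RateModel, code: int) -> np.ndarray:
    if code == MISSING:
        return np.ones(model.n_states)
    vec = np.zeros(model.n_states)
    vec[code] = 1.0
    return vec


def _tip_codes(tree: RootedPhylogeny, column: AlignmentColumn | None) -> dict[int, int]:
    if column is None:
        return {int(t): MISSING for t in tree.tip_ids}
    lab_to_pos = {lab: k for k, lab in enumerate(column.labels)}
    codes = {}
    for t in tree.tip_ids:
        lab = tree.labels[int(t)]
        if lab not in lab_to_pos:
            raise KeyError(f"tree tip {lab!r} absent from the alignment column")
        codes[int(t)] = int(column.codes[lab_to_pos[lab]])
    return codes


def _rescale(arr: np.ndarray, logscale: float) -> tuple[np.ndarray, float]:
    m = arr.max()
    if m <= 0.0:
        raise ImpossibleDataError("message vanished: column has zero likelihood")
    return arr / m, logscale + math.log(m)


def _prop_up(arr: np.ndarray, K) -> np.ndarray:
    """Move a conditional message up a branch (no-substitution split at i=0)."""
    colsum = arr.sum(axis=0)
    out = arr * K.I[None, :]
    out[0] += K.P @ colsum - K.I * colsum
    return out


def _prop_down(arr: np.ndarray, K) -> np.ndarray:
    """Move a joint message down a branch (transition direction parent->child)."""
    colsum = arr.sum(axis=0)
    out = arr * K.I[None, :]
    out[0] += K.P.T @ colsum - K.I * colsum
    return out


def _convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-state convolution over the PIBD count: disjoint tip sets add."""
    na, nb = a.shape[0] - 1, b.shape[0] - 1
    out = np.zeros((na + nb + 1, a.shape[1]))
    for i in range(na + 1):
        out[i : i + nb + 1] += a[i][None, :] * b
    return out


# -- the algorithm ---------------------------------------------------------


def updown(
    tree: RootedPhylogeny,
    model: RateModel,
    column: AlignmentColumn | None = None,
) -> PibdResult:
    """Run the full up-down pruning pass.

    With ``column=None`` (or an all-missing column) the result is the
    unconditional PIBD distribution of every tip; otherwise distributions
    are conditioned on the observed characters.
    """
    conditional = column is not None and not column.is_empty
    N = tree.n_tips
    B = model.n_states
    pi = model.pi
    codes = _tip_codes(tree, column)

    if N == 1:
        only = int(tree.tip_ids[0])
        p = np.zeros(2)
        p[1] = 1.0
        return PibdResult(
            [PibdDistribution(tree.labels[only], p, conditional)],
            likelihood=float(pi[codes[only]]) if codes[only] != MISSING else 1.0,
            conditional=conditional,
        )

    kern = {
        int(v): branch_kernel(model, float(tree.blen[v]))
        for v in range(tree.n_nodes)
        if v != tree.root
    }

    # -- up phase: post-order -----------------------------------------
    up: dict[int, tuple[np.ndarray, float]] = {}
    up_above: dict[int, tuple[np.ndarray, float]] = {}  # child subtree, seen from parent
    for v in tree.postorder:
        v = int(v)
        if tree.is_tip(v):
            arr = np.zeros((2, B))
            arr[1] = _tip_like(model, codes[v])
            up[v] = (arr, 0.0)
        else:
            c1, c2 = tree.children[v]
            for c in (c1, c2):
                a, ls = up[c]
                up_above[c] = _rescale(_prop_up(a, kern[c]), ls)
            (a1, l1), (a2, l2) = up_above[c1], up_above[c2]
            up[v] = _rescale(_convolve(a1, a2), l1 + l2)

    root_arr, root_ls = up[tree.root]
    likelihood = float((pi[None, :] * root_arr).sum() * math.exp(root_ls))
    if conditional and likelihood <= 0.0:
        raise ImpossibleDataError("column has zero likelihood under the model")

    # -- down phase: pre-order ----------------------------------------
    down: dict[int, tuple[np.ndarray, float]] = {
        tree.root: (pi.reshape(1, B).copy(), 0.0)
    }
    for v in tree.preorder:
        v = int(v)
        if tree.is_tip(v):
            continue
        c1, c2 = tree.children[v]
        dv, dls = down[v]
        for c, sib in ((c1, c2), (c2, c1)):
            s_arr, s_ls = up_above[sib]
            src = _convolve(dv, s_arr)
            down[c] = _rescale(_prop_down(src, kern[c]), dls + s_ls)

    # -- finalise at the tips -----------------------------------------
    dists = []
    for t in tree.tip_ids:
        t = int(t)
        d_arr, _ = down[t]
        joint = d_arr * _tip_like(model, codes[t])[None, :]
        p = np.zeros(N + 1)
        per_i = joint.sum(axis=1)
        p[1 : 1 + len(per_i)] = per_i[:N]
        total = p.sum()
        if total <= 0.0:
            raise ImpossibleDataError("column has zero likelihood under the model")
        p /= total
        dists.append(PibdDistribution(tree.labels[t], p, conditional))
    return PibdResult(dists, likelihood=likelihood, conditional=conditional)


def pibd_distributions(
    tree: RootedPhylogeny,
    model: RateModel,
    column: AlignmentColumn | None = None,
) -> list[PibdDistribution]:
    """Per-tip PIBD-class-size distributions (Up then Down phase)."""
    return updown(tree, model, column).distributions


def pns_weights(tree: RootedPhylogeny, model: RateModel) -> WeightSet:
    """Exact unconditional novelty scores ``w_s`` with the ESN attached."""
    result = updown(tree, model, None)
    return result.weight_set("pns", metadata={"model": model.name})


def conditional_pns_weights(
    tree: RootedPhylogeny, model: RateModel, column: AlignmentColumn
) -> WeightSet:
    """Column-conditional novelty scores ``w_s^D``."""
    result = updown(tree, model, column)
    return result.weight_set(
        "pns_conditional", column_index=column.index, metadata={"model": model.name}
    )


def esn(
    tree: RootedPhylogeny,
    model: RateModel,
    column: AlignmentColumn | None = None,
) -> float:
    """Effective sequence number ``T`` (or ``T^D``).

    The unconditional case uses a linear-time pruning recursion over the
    identity ``T = E[#PIBD classes among tips]``: a class is counted at its
    root-most member, which requires a substitution on the branch above
    (or the tree root) and at least one substitution-free connection to a
    tip below.  The conditional case falls back to summing exact
    conditional weights.
    """
    if column is not None and not column.is_empty:
        return conditional_pns_weights(tree, model, column).esn
    if tree.n_tips == 1:
        return 1.0
    pi = model.pi
    # a[v][j]: P(no tip below v is substitution-free-connected to v | state j)
    a: dict[int, np.ndarray] = {}
    kern = {}
    total = 0.0
    for v in tree.postorder:
        v = int(v)
        if tree.is_tip(v):
            a[v] = np.zeros(model.n_states)
        else:
            acc = np.ones(model.n_states)
            for c in tree.children[v]:
                kern[c] = branch_kernel(model, float(tree.blen[c]))
                acc = acc * (1.0 - kern[c].I * (1.0 - a[c]))
            a[v] = acc
        if v == tree.root:
            total += float(pi @ (1.0 - a[v]))
        else:
            if v not in kern:
                kern[v] = branch_kernel(model, float(tree.blen[v]))
            total += float(pi @ ((1.0 - kern[v].I) * (1.0 - a[v])))
    return total


def fast_pns_weights(tree: RootedPhylogeny, model: RateModel) -> WeightSet:
    """O(N) approximate scores ``1 / E[i(s)]`` (reciprocal of the mean
    PIBD-class size rather than the mean of the reciprocal).

    The probability that two tips at path distance ``d`` are PIBD is
    ``sum_j pi[j] exp(Q[j, j] * d)`` for a stationary model, so
    ``E[i(s)] = 1 + sum_{s' != s} sum_j pi[j] exp(Q[j, j] d(s, s'))``.
    The inner sums are accumulated for all tips at once by one post-order
    and one pre-order sweep of per-state no-substitution mass; the O(N^2)
    pairwise sum is only ever used as a test oracle.

    By Jensen's inequality ``E[1/i] >= 1/E[i]``, so these never exceed the
    exact scores.
    """
    pi = model.pi
    B = model.n_states
    if tree.n_tips == 1:
        lab = tree.labels[int(tree.tip_ids[0])]
        return WeightSet("pns_fast", {lab: 1.0}, metadata={"model": model.name})
    I = {
        int(v): model.no_substitution_probabilities(float(tree.blen[v]))
        for v in range(tree.n_nodes)
        if v != tree.root
    }
    # u[v][j] = sum over tips below v of exp(Qjj * d(v, tip))
    u: dict[int, np.ndarray] = {}
    for v in tree.postorder:
        v = int(v)
        if tree.is_tip(v):
            u[v] = np.ones(B)
        else:
            u[v] = sum(I[c] * u[c] for c in tree.children[v])
    # g[v][j] = the same sum over tips *not* below v
    g: dict[int, np.ndarray] = {tree.root: np.zeros(B)}
    for v in tree.preorder:
        v = int(v)
        if tree.is_tip(v):
            continue
        for c in tree.children[v]:
            sib_mass = sum(
                I[c2] * u[c2] for c2 in tree.children[v] if c2 != c
            )
            g[c] = I[c] * (g[v] + sib_mass)
    weights = {}
    for t in tree.tip_ids:
        t = int(t)
        expected_i = 1.0 + float(pi @ g[t])
        weights[tree.labels[t]] = 1.0 / expected_i
    return WeightSet("pns_fast", weights, metadata={"model": model.name})
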