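"""Independent, deliberately slow estimators of PIBD distributions.

These exist to validate the up-down dynamic program, so they share no code
path with it:

* :func:`enumerate_histories` -- fully naive enumeration of every
  (state assignment, substitution indicator) mutational history; feasible
  only for 2-3 tips, and itself the oracle for the next layer.
* :func:`brute_force_pibd` -- exhaustive enumeration over per-branch
  substitution-indicator patterns (``2^branches`` of them), summing over
  states exactly on the contracted component tree; exact for trees of up
  to ~6 tips.
* :func:`simulate_pns` / :func:`simulate_conditional_pns` -- Monte-Carlo
  with explicit event recording (endpoint-only simulation cannot tell
  identity by descent from identity by state), with standard errors.
* :func:`felsenstein_likelihood` -- an ordinary pruning likelihood, coded
  independently of the PIBD machinery, for the normaliser cross-check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .alignment import MISSING, AlignmentColumn
from .models import RateModel, branch_kernel
from .pns import PibdDistribution, PibdResult, WeightSet, _tip_codes, _tip_like
from .tree import RootedPhylogeny


class BruteForceCapError(ValueError):
    """Tree too large for exhaustive enumeration; use the simulation oracle."""


class RejectionAcceptanceError(RuntimeError):
    """Rejection sampling would accept too rarely to be useful."""


@dataclass(frozen=True)
class MutationalHistory:
    """One complete history: states everywhere, per-branch event indicator.

    ``substituted`` holds the child-node ids of branches that carry at
    least one substitution event.  The PIBD classes are the connected
    components of the substitution-free branch graph; ``class_sizes`` maps
    each tip label to the size of its class.  ``weight`` is the history's
    probability (zero-weight histories are skipped by the enumerator).
    """

    states: tuple[int, ...]
    substituted: frozenset[int]
    weight: float
    class_sizes: dict


def felsenstein_likelihood(
    tree: RootedPhylogeny, model: RateModel, column: AlignmentColumn | None
) -> float:
    """Standard pruning likelihood of one column (1.0 for an empty column)."""
    codes = _tip_codes(tree, column)
    logscale = 0.0
    partial: dict[int, np.ndarray] = {}
    for v in tree.postorder:
        v = int(v)
        if tree.is_tip(v):
            partial[v] = _tip_like(model, codes[v])
        else:
            acc = np.ones(model.n_states)
            for c in tree.children[v]:
                P = model.transition_matrix(float(tree.blen[c]))
                acc = acc * (P @ partial[c])
            m = acc.max()
            if m <= 0:
                return 0.0
            partial[v] = acc / m
            logscale += math.log(m)
    return float(model.pi @ partial[tree.root] * math.exp(logscale))


# -- component machinery shared by the exhaustive oracles ------------------


def _tip_class_sizes(tree: RootedPhylogeny, substituted) -> tuple[np.ndarray, dict]:
    """Component label per node and per-tip class size, given the set of
    substituted branches (child-node ids)."""
    comp = np.arange(tree.n_nodes)
    for v in tree.preorder:
        v = int(v)
        p = tree.parent[v]
        if p >= 0 and v not in substituted:
            comp[v] = comp[p]
    tip_comp = comp[tree.tip_ids]
    sizes = {}
    for t, c in zip(tree.tip_ids, tip_comp):
        sizes[tree.labels[int(t)]] = int(np.sum(tip_comp == c))
    return comp, sizes


def _pattern_probability(tree, model, kern, codes, comp, substituted) -> float:
    """P(data, pattern): exact sum over states on the contracted component tree.

    Within a component every node shares one state; a substitution-free
    branch contributes ``I_t[j]``, a substituted branch between component
    states ``j`` (parent) and ``k`` (child) contributes
    ``P_t[j, k] - delta(j, k) I_t[j]``.
    """
    B = model.n_states
    # G[c][j]: probability of everything at/below component c given state j
    G: dict[int, np.ndarray] = {}
    # components complete in postorder of their root-most node
    members: dict[int, list[int]] = {}
    for v in tree.postorder:
        members.setdefault(int(comp[v]), []).append(int(v))
    for v in tree.postorder:
        v = int(v)
        if comp[v] != v:
            continue  # v is not a component root
        vec = np.ones(B)
        for m in members[v]:
            if tree.is_tip(m) and codes[m] != MISSING:
                ind = np.zeros(B)
                ind[codes[m]] = 1.0
                vec = vec * ind
            for c in tree.children[m]:
                K = kern[c]
                if c in substituted:
                    M = K.P - np.diag(K.I)
                    vec = vec * (M @ G[int(comp[c])])
                else:
                    vec = vec * K.I  # internal no-substitution branch
        G[v] = vec
    return float(model.pi @ G[int(comp[tree.root])])


def brute_force_pibd(
    tree: RootedPhylogeny,
    model: RateModel,
    column: AlignmentColumn | None = None,
    max_tips: int = 6,
) -> PibdResult:
    """Exact PIBD distributions by exhausting all substitution patterns.

    Enumerates every assignment of "at least one event" / "no event" to
    every branch (``2^(#branches)`` patterns); for each, the tip partition
    is fixed and the probability is summed over states exactly.  Cost is
    exponential, hence the hard cap.
    """
    if tree.n_tips > max_tips:
        raise BruteForceCapError(
            f"{tree.n_tips} tips exceeds the brute-force cap of {max_tips}; "
            "use the simulation oracle instead"
        )
    conditional = column is not None and not column.is_empty
    codes = _tip_codes(tree, column)
    N = tree.n_tips
    branches = [int(v) for v in range(tree.n_nodes) if v != tree.root]
    kern = {v: branch_kernel(model, float(tree.blen[v])) for v in branches}
    accum = {tree.labels[int(t)]: np.zeros(N + 1) for t in tree.tip_ids}
    total = 0.0
    for bits in itertools.product((False, True), repeat=len(branches)):
        substituted = {v for v, b in zip(branches, bits) if b}
        comp, sizes = _tip_class_sizes(tree, substituted)
        prob = _pattern_probability(tree, model, kern, codes, comp, substituted)
        if prob <= 0.0:
            continue
        total += prob
        for lab, i in sizes.items():
            accum[lab][i] += prob
    if total <= 0.0:
        raise ValueError("column has zero likelihood under the model")
    dists = [
        PibdDistribution(lab, vec / total, conditional)
        for lab, vec in accum.items()
    ]
    return PibdResult(dists, likelihood=total, conditional=conditional)


def enumerate_histories(
    tree: RootedPhylogeny,
    model: RateModel,
    column: AlignmentColumn | None = None,
    max_tips: int = 3,
):
    """Yield every positive-weight :class:`MutationalHistory`.

    Triple-nested and unashamedly exponential (``B^nodes * 2^branches``);
    this is the ground truth that validates :func:`brute_force_pibd` on
    trees of 2-3 tips.  Unconditional weights sum to 1; conditional on a
    column they sum to its likelihood.
    """
    if tree.n_tips > max_tips:
        raise BruteForceCapError(
            f"{tree.n_tips} tips exceeds the history-enumeration cap of {max_tips}"
        )
    codes = _tip_codes(tree, column)
    B = model.n_states
    n = tree.n_nodes
    branches = [v for v in range(n) if v != tree.root]
    kern = {v: branch_kernel(model, float(tree.blen[v])) for v in branches}
    for states in itertools.product(range(B), repeat=n):
        ok = all(
            codes[int(t)] == MISSING or states[int(t)] == codes[int(t)]
            for t in tree.tip_ids
        )
        if not ok:
            continue
        base = float(model.pi[states[tree.root]])
        for bits in itertools.product((False, True), repeat=len(branches)):
            substituted = frozenset(v for v, b in zip(branches, bits) if b)
            w = base
            for v in branches:
                j, k = states[tree.parent[v]], states[v]
                K = kern[v]
                if v in substituted:
                    w *= K.P[j, k] - (K.I[j] if j == k else 0.0)
                elif j == k:
                    w *= K.I[j]
                else:
                    w = 0.0
                    break
                if w <= 0.0:
                    break
            if w <= 0.0:
                continue
            _, sizes = _tip_class_sizes(tree, substituted)
            yield MutationalHistory(tuple(states), substituted, w, sizes)


# -- Monte-Carlo oracles ---------------------------------------------------

_CHUNK = 1 << 14  # fixed internal batch so results only depend on the seed


def _gillespie_branch(rng, start, t, Qdiag, jump_cum):
    """Vectorised event simulation along one branch.

    Exponential waiting times at rate ``-Q[j, j]``, jump probabilities
    ``Q[j, k] / -Q[j, j]``; only the end state and whether any event
    occurred are retained.
    """
    states = start.copy()
    any_sub = np.zeros(len(states), dtype=bool)
    t_left = np.full(len(states), float(t))
    active = np.nonzero(Qdiag[states] < 0)[0]
    while active.size:
        rates = -Qdiag[states[active]]
        waits = rng.exponential(1.0, size=active.size) / rates
        jumping = waits < t_left[active]
        idx = active[jumping]
        if idx.size == 0:
            break
        t_left[idx] -= waits[jumping]
        u = rng.random(idx.size)
        states[idx] = (u[:, None] > jump_cum[states[idx]]).sum(axis=1)
        any_sub[idx] = True
        active = idx[Qdiag[states[idx]] < 0]
    return states, any_sub


def _jump_cumulative(model: RateModel) -> tuple[np.ndarray, np.ndarray]:
    Q = model.Q
    Qdiag = np.diag(Q).copy()
    J = Q.copy()
    np.fill_diagonal(J, 0.0)
    rates = -Qdiag
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(rates[:, None] > 0, J / np.where(rates[:, None] > 0, rates[:, None], 1.0), 0.0)
    return Qdiag, np.cumsum(J, axis=1)


def _class_sizes_from_events(tree, node_states, node_sub):
    """Per-tip PIBD class sizes for a batch of simulated histories."""
    n_iter = next(iter(node_states.values())).shape[0]
    anc = {tree.root: np.full(n_iter, tree.root, dtype=np.int64)}
    for v in tree.preorder:
        v = int(v)
        p = tree.parent[v]
        if p < 0:
            continue
        anc[v] = np.where(node_sub[v], v, anc[int(p)])
    tip_anc = np.stack([anc[int(t)] for t in tree.tip_ids])  # (N, n_iter)
    sizes = (tip_anc[None, :, :] == tip_anc[:, None, :]).sum(axis=1)
    return sizes  # (N, n_iter)


def _weights_from_scores(tree, sums, sumsq, n, scheme, extra=None) -> WeightSet:
    labels = tree.tip_labels
    weights, stderr = {}, {}
    for k, lab in enumerate(labels):
        mean = sums[k] / n
        var = max(sumsq[k] / n - mean**2, 0.0)
        weights[lab] = float(mean)
        stderr[lab] = float(math.sqrt(var / n))
    meta = {"iterations": int(n), "stderr": stderr}
    if extra:
        meta.update(extra)
    return WeightSet(scheme, weights, metadata=meta)


def simulate_pns(
    tree: RootedPhylogeny, model: RateModel, iterations: int, seed
) -> WeightSet:
    """Monte-Carlo novelty scores from event-recording simulation.

    Each iteration samples a root state from the equilibrium, simulates
    substitution events down every branch, scores each tip ``1/i`` for its
    PIBD-class size ``i``, and averages.  Standard errors are attached in
    ``metadata['stderr']``.  Deterministic given ``seed``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    Qdiag, jump_cum = _jump_cumulative(model)
    N = tree.n_tips
    sums = np.zeros(N)
    sumsq = np.zeros(N)
    done = 0
    while done < iterations:
        m = min(_CHUNK, iterations - done)
        node_states = {
            tree.root: rng.choice(model.n_states, size=m, p=model.pi)
        }
        node_sub = {}
        for v in tree.preorder:
            v = int(v)
            p = tree.parent[v]
            if p < 0:
                continue
            node_states[v], node_sub[v] = _gillespie_branch(
                rng, node_states[int(p)], tree.blen[v], Qdiag, jump_cum
            )
        sizes = _class_sizes_from_events(tree, node_states, node_sub)
        scores = 1.0 / sizes
        sums += scores.sum(axis=1)
        sumsq += (scores**2).sum(axis=1)
        done += m
    return _weights_from_scores(tree, sums, sumsq, iterations, "pns_mc")


def _sample_states_given_column(tree, model, column, rng, m):
    """Joint posterior draw of all node states given the column (up-down
    sampling: partial likelihoods up, ancestral sampling down)."""
    codes = _tip_codes(tree, column)
    B = model.n_states
    partial = {}
    for v in tree.postorder:
        v = int(v)
        if tree.is_tip(v):
            partial[v] = _tip_like(model, codes[v])
        else:
            acc = np.ones(B)
            for c in tree.children[v]:
                P = model.transition_matrix(float(tree.blen[c]))
                acc = acc * (P @ partial[c])
            mx = acc.max()
            if mx <= 0:
                raise ValueError("column has zero likelihood under the model")
            partial[v] = acc / mx
    root_p = model.pi * partial[tree.root]
    root_p = root_p / root_p.sum()
    states = {tree.root: rng.choice(B, size=m, p=root_p)}
    for v in tree.preorder:
        v = int(v)
        p = tree.parent[v]
        if p < 0:
            continue
        P = model.transition_matrix(float(tree.blen[v]))
        probs = P[states[int(p)]] * partial[v][None, :]
        probs = probs / probs.sum(axis=1, keepdims=True)
        u = rng.random(m)
        states[v] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    return states


def simulate_conditional_pns(
    tree: RootedPhylogeny,
    model: RateModel,
    column: AlignmentColumn,
    iterations: int,
    seed,
    mode: str = "updown",
) -> WeightSet:
    """Monte-Carlo conditional novelty scores ``w_s^D``.

    ``mode='updown'`` samples internal states from their joint posterior
    given the column, then draws "no substitution" on every branch with
    equal endpoint states with probability ``I_t[j] / P_t[j, j]`` (a branch
    with unequal endpoints always carries a substitution).

    ``mode='rejection'`` simulates unconditionally with event recording and
    discards iterations that do not reproduce the column; it refuses to run
    when the acceptance probability (the column likelihood) is below 1e-6.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    N = tree.n_tips
    codes = _tip_codes(tree, column)

    if mode == "updown":
        kern = {
            int(v): branch_kernel(model, float(tree.blen[v]))
            for v in range(tree.n_nodes)
            if v != tree.root
        }
        sums = np.zeros(N)
        sumsq = np.zeros(N)
        done = 0
        while done < iterations:
            m = min(_CHUNK, iterations - done)
            states = _sample_states_given_column(tree, model, column, rng, m)
            node_sub = {}
            for v in range(tree.n_nodes):
                if v == tree.root:
                    continue
                j_par = states[int(tree.parent[v])]
                j_child = states[v]
                equal = j_par == j_child
                K = kern[v]
                with np.errstate(invalid="ignore", divide="ignore"):
                    p_nosub = np.where(
                        equal, K.I[j_child] / np.maximum(K.P[j_child, j_child], 1e-300), 0.0
                    )
                node_sub[v] = rng.random(m) >= p_nosub
            sizes = _class_sizes_from_events(tree, states, node_sub)
            scores = 1.0 / sizes
            sums += scores.sum(axis=1)
            sumsq += (scores**2).sum(axis=1)
            done += m
        return _weights_from_scores(
            tree, sums, sumsq, iterations, "pns_conditional_mc", {"mode": "updown"}
        )

    if mode == "rejection":
        acceptance = felsenstein_likelihood(tree, model, column)
        if acceptance < 1e-6:
            raise RejectionAcceptanceError(
                f"column likelihood {acceptance:.3g} < 1e-6: rejection sampling "
                "would almost never accept; use mode='updown'"
            )
        Qdiag, jump_cum = _jump_cumulative(model)
        tip_codes_arr = np.array([codes[int(t)] for t in tree.tip_ids])
        sums = np.zeros(N)
        sumsq = np.zeros(N)
        accepted = 0
        done = 0
        while done < iterations:
            m = min(_CHUNK, iterations - done)
            node_states = {tree.root: rng.choice(model.n_states, size=m, p=model.pi)}
            node_sub = {}
            for v in tree.preorder:
                v = int(v)
                p = tree.parent[v]
                if p < 0:
                    continue
                node_states[v], node_sub[v] = _gillespie_branch(
                    rng, node_states[int(p)], tree.blen[v], Qdiag, jump_cum
                )
            tip_states = np.stack([node_states[int(t)] for t in tree.tip_ids])
            match = np.ones(m, dtype=bool)
            for k in range(N):
                if tip_codes_arr[k] != MISSING:
                    match &= tip_states[k] == tip_codes_arr[k]
            if match.any():
                sizes = _class_sizes_from_events(
                    tree,
                    {v: s[match] for v, s in node_states.items()},
                    {v: s[match] for v, s in node_sub.items()},
                )
                scores = 1.0 / sizes
                sums += scores.sum(axis=1)
                sumsq += (scores**2).sum(axis=1)
                accepted += int(match.sum())
            done += m
        if accepted == 0:
            raise RejectionAcceptanceError(
                "no iteration matched the column; increase iterations or use mode='updown'"
            )
        return _weights_from_scores(
            tree,
            sums,
            sumsq,
            accepted,
            "pns_conditional_mc",
            {"mode": "rejection", "acceptance": accepted / done},
        )

    raise ValueError(f"unknown mode {mode!r}; expected 'updown' or 'rejection'")
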