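"""Synthetic benchmark: alignments with known per-column equilibria.

The generator mirrors a standard profiling benchmark: columns evolve
independently on a fixed tree; 80% of columns are "background" (one shared
equilibrium distribution, here the neutral mutational bias), 20% are
"selected" with a column-specific equilibrium drawn from a sparse
symmetric Dirichlet.  Variants rescale the tree, switch to amino acids
(LG), attach an over-sampled coalescent clade to one tip (biased taxon
sampling), or use a strongly non-ultrametric ladder tree.  Accuracy is the
per-column Euclidean distance between true and inferred frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment
from .classic import gsc94_weights, hh94_weights
from .freqs import (
    dirichlet_posterior,
    observed_frequencies,
    posterior_mean,
    weighted_frequencies,
)
from .models import RateModel, hky85, lg
from .pns import WeightSet, conditional_pns_weights, fast_pns_weights, pns_weights
from .tree import RootedPhylogeny, _Node, attach_coalescent_clade, random_tree


@dataclass(frozen=True)
class CladeSpec:
    """Over-sampled clade: ``n_extra`` coalescent tips appended to ``tip``."""

    tip: str
    n_extra: int
    mean_coalescent_time: float = 0.001


@dataclass
class ScenarioConfig:
    """One benchmark scenario.

    Defaults follow the nucleotide design: HKY85 with kappa = 3, background
    equilibrium (0.3, 0.2, 0.2, 0.3) for A, C, G, T, 80% background
    columns, selected-column equilibria from Dirichlet(0.1) (0.02 for the
    amino-acid variant), 10 replicates of 1000 columns.
    """

    tree: RootedPhylogeny
    model: str = "HKY85"
    kappa: float = 3.0
    background_pi: tuple = (0.3, 0.2, 0.2, 0.3)
    tree_scale: float = 1.0
    columns_total: int = 1000
    selected_fraction: float = 0.2
    dirichlet_alpha: float = 0.1
    clade: CladeSpec | None = None
    seed: int = 0
    replicates: int = 10
    exact_split: bool = True

    def __post_init__(self):
        if not 0.0 <= self.selected_fraction <= 1.0:
            raise ValueError("selected_fraction must lie in [0, 1]")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.columns_total < 1:
            raise ValueError("columns_total must be >= 1")

    def make_model(self, pi=None) -> RateModel:
        pi = self.background_pi if pi is None else pi
        if self.model.upper() == "HKY85":
            return hky85(self.kappa, pi)
        if self.model.upper() == "LG":
            return lg(pi)
        raise ValueError(f"unsupported simulation model {self.model!r}")


@dataclass(frozen=True)
class SimulatedColumnTruth:
    """Regime and true equilibrium used to simulate one column."""

    column: int
    regime: str  # background | selected
    pi: np.ndarray


@dataclass
class SimulatedReplicate:
    """Everything one replicate produced: the tree actually used, the
    alignment, and the per-column truth."""

    tree: RootedPhylogeny
    alignment: Alignment
    truths: list[SimulatedColumnTruth]


def _simulate_columns(tree: RootedPhylogeny, model: RateModel, rng, n_cols: int):
    """Endpoint states at the tips for ``n_cols`` i.i.d. columns.

    Root states are drawn from the equilibrium; each branch then samples
    the child state from the parent's row of ``P_t`` (endpoint simulation
    is sufficient here -- the alignment only records tip characters).
    """
    B = model.n_states
    states = {tree.root: rng.choice(B, size=n_cols, p=model.pi)}
    for v in tree.preorder:
        v = int(v)
        p = tree.parent[v]
        if p < 0:
            continue
        P = model.transition_matrix(float(tree.blen[v]))
        cum = np.cumsum(P, axis=1)
        u = rng.random(n_cols)
        states[v] = (u[:, None] > cum[states[int(p)]]).sum(axis=1)
    return np.stack([states[int(t)] for t in tree.tip_ids])  # (N, n_cols)


def build_tree(config: ScenarioConfig, rng) -> RootedPhylogeny:
    """Apply the scenario's tree transformations (scaling, clade grafting)."""
    tree = config.tree
    if config.tree_scale != 1.0:
        tree = tree.scale(config.tree_scale)
    if config.clade is not None:
        tree = attach_coalescent_clade(
            tree,
            config.clade.tip,
            config.clade.n_extra,
            config.clade.mean_coalescent_time,
            rng,
        )
    return tree


def simulate_alignment(
    config: ScenarioConfig, replicate: int = 0
) -> SimulatedReplicate:
    """Simulate one replicate alignment with recorded per-column truth.

    Deterministic given ``(config.seed, replicate)``.  With
    ``exact_split=True`` exactly ``round(columns_total * selected_fraction)``
    columns are selected; otherwise the regime is Bernoulli per column.
    Column order is randomised so regimes are interleaved.
    """
    rng = np.random.default_rng([config.seed, replicate])
    tree = build_tree(config, rng)
    n_total = config.columns_total
    if config.exact_split:
        n_sel = int(round(n_total * config.selected_fraction))
        regimes = np.array([False] * (n_total - n_sel) + [True] * n_sel)
        rng.shuffle(regimes)
    else:
        regimes = rng.random(n_total) < config.selected_fraction

    B = len(config.background_pi)
    codes = np.empty((tree.n_tips, n_total), dtype=np.int64)
    truths: list[SimulatedColumnTruth] = [None] * n_total  # type: ignore

    bg_idx = np.nonzero(~regimes)[0]
    bg_model = config.make_model()
    if bg_idx.size:
        codes[:, bg_idx] = _simulate_columns(tree, bg_model, rng, bg_idx.size)
    for k in bg_idx:
        truths[k] = SimulatedColumnTruth(int(k), "background", bg_model.pi)

    for k in np.nonzero(regimes)[0]:
        # sparse Dirichlet equilibria can put ~0 mass on states; floor them
        # so the per-column rate matrix stays a valid irreducible chain
        pi_k = rng.dirichlet(np.full(B, config.dirichlet_alpha))
        pi_k = np.maximum(pi_k, 1e-9)
        pi_k = pi_k / pi_k.sum()
        model_k = config.make_model(pi_k)
        codes[:, k] = _simulate_columns(tree, model_k, rng, 1)[:, 0]
        truths[int(k)] = SimulatedColumnTruth(int(k), "selected", pi_k)

    alignment = Alignment(tree.tip_labels, codes, bg_model.states)
    return SimulatedReplicate(tree, alignment, truths)


def frequency_error(truth, estimate) -> float:
    """Euclidean distance between true and inferred frequency vectors."""
    t = truth.pi if isinstance(truth, SimulatedColumnTruth) else np.asarray(truth, float)
    e = getattr(estimate, "freqs", None)
    e = np.asarray(estimate if e is None else e, dtype=float)
    return float(np.linalg.norm(t - e))


_POINT_SCHEMES = ("counts", "hh94", "gsc94", "pns", "pns_fast", "pns_conditional")


def _column_estimates(scheme, rep: SimulatedReplicate, model: RateModel):
    """Yield one FrequencyEstimate per column under the given scheme."""
    base = scheme.removeprefix("bayes:")
    bayes = scheme.startswith("bayes:")
    if base not in _POINT_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    weights: WeightSet | None = None
    if base == "hh94":
        weights = hh94_weights(rep.alignment)
    elif base == "gsc94":
        weights = gsc94_weights(rep.tree)
    elif base == "pns":
        weights = pns_weights(rep.tree, model)
    elif base == "pns_fast":
        weights = fast_pns_weights(rep.tree, model)
    for col in rep.alignment:
        if base == "pns_conditional":
            weights = conditional_pns_weights(rep.tree, model, col)
        if bayes:
            post = dirichlet_posterior(col, weights)
            yield posterior_mean(post)
        elif weights is None:
            yield observed_frequencies(col)
        else:
            yield weighted_frequencies(col, weights)


def run_benchmark(config: ScenarioConfig, schemes) -> pd.DataFrame:
    """Score frequency-inference accuracy per scheme, replicate and regime.

    The tree handed to tree-based schemes is the true simulation tree (the
    external tree-inference step of a real-data pipeline is out of scope; a
    pre-inferred tree can be substituted by building the config around it).
    Returns a tidy frame with mean and median Euclidean error.
    """
    rows = []
    for r in range(config.replicates):
        rep = simulate_alignment(config, replicate=r)
        model = config.make_model()
        for scheme in schemes:
            errors = np.array(
                [
                    frequency_error(truth, est)
                    for truth, est in zip(
                        rep.truths, _column_estimates(scheme, rep, model)
                    )
                ]
            )
            regimes = np.array([t.regime for t in rep.truths])
            for regime in ("background", "selected"):
                mask = regimes == regime
                if not mask.any():
                    continue
                rows.append(
                    {
                        "replicate": r,
                        "scheme": scheme,
                        "regime": regime,
                        "n_columns": int(mask.sum()),
                        "mean_error": float(errors[mask].mean()),
                        "median_error": float(np.median(errors[mask])),
                    }
                )
    return pd.DataFrame(rows)


def biased_sampling_scenario(
    seed: int = 0, columns_total: int = 200, replicates: int = 10
) -> ScenarioConfig:
    """Taxon-oversampling benchmark: diverse backbone + near-identical clade.

    A 20-tip backbone (fixed random topology, mean branch length 1.0, so
    backbone tips are deeply diverged and close to independent draws from
    each column's equilibrium) with a 50-tip coalescent clade of mean
    pairwise coalescence time 0.001 grafted onto one tip.  Unweighted
    counts are dominated by the 51 near-identical clade rows; weighting
    restores the backbone's information.
    """
    base = random_tree(20, np.random.default_rng(42), mean_branch=1.0)
    return ScenarioConfig(
        tree=base,
        columns_total=columns_total,
        seed=seed,
        replicates=replicates,
        clade=CladeSpec(tip="T1", n_extra=50, mean_coalescent_time=0.001),
    )


def non_ultrametric_scenario(
    seed: int = 0, columns_total: int = 200, replicates: int = 10
) -> ScenarioConfig:
    """Strongly non-ultrametric (ladder-tree) benchmark.

    Tip-to-root distances spread over a 20-fold range, as in serially
    sampled virus phylogenies; the regime where GSC94's proportional
    branch-length distribution concentrates weight on the most recent
    tips and degrades, while novelty scores do not.
    """
    return ScenarioConfig(
        tree=caterpillar_tree(20),
        columns_total=columns_total,
        seed=seed,
        replicates=replicates,
    )


def caterpillar_tree(
    n_tips: int = 20,
    internode: float = 0.1,
    pendant: float = 0.01,
    jitter: float = 0.0,
    seed: int = 0,
) -> RootedPhylogeny:
    """A strongly non-ultrametric ladder tree (influenza-like sampling).

    The backbone is a chain of ``internode``-length branches with one
    short-pendant tip at every rung, so tip-to-root distances range from
    ``pendant`` to ``(n_tips - 1) * internode + pendant``.  Optional
    multiplicative jitter (uniform in ``1 +- jitter``) is seeded.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)

    def length(base):
        if jitter <= 0:
            return base
        return base * float(rng.uniform(1.0 - jitter, 1.0 + jitter))

    root = _Node()
    current = root
    for k in range(1, n_tips - 1):
        tip = _Node(label=f"T{k}", length=length(pendant))
        inner = _Node(length=length(internode))
        current.children = [tip, inner]
        current = inner
    current.children = [
        _Node(label=f"T{n_tips - 1}", length=length(pendant)),
        _Node(label=f"T{n_tips}", length=length(pendant)),
    ]
    return RootedPhylogeny(root)
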