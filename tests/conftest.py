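import numpy as np
import pytest

import phylonovelty as pv


@pytest.fixture
def jc():
    return pv.jc69()


@pytest.fixture
def hky():
    return pv.hky85(3.0, (0.3, 0.2, 0.2, 0.3))


def two_tip_tree(t, split=0.5):
    """A rooted two-tip JC-style tree with total tip-to-tip path t."""
    return pv.read_newick(f"(A:{t * split:.12g},B:{t * (1 - split):.12g});")


def random_reversible_model(rng, n_states=4):
    """Random reversible model from random exchangeabilities and frequencies."""
    S = rng.uniform(0.2, 2.0, size=(n_states, n_states))
    S = (S + S.T) / 2
    pi = rng.dirichlet(np.full(n_states, 2.0))
    states = tuple("ACGT"[:n_states]) if n_states <= 4 else tuple(
        pv.models.AMINO_ACIDS[:n_states]
    )
    return pv.custom_model(states, exchangeabilities=S, pi=pi)


def random_column(tree, model, rng, p_missing=0.25):
    """Random observed column over the tree's tips, with missing entries."""
    codes = np.array(
        [
            -1 if rng.random() < p_missing else int(rng.integers(model.n_states))
            for _ in tree.tip_labels
        ]
    )
    return pv.AlignmentColumn(
        labels=tuple(tree.tip_labels), codes=codes, states=tuple(model.states)
    )


def dist_map(result):
    return {d.label: d for d in result.distributions}
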