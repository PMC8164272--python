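"""Reference implementations of the HH94 and GSC94 weighting schemes.

HH94 (Henikoff & Henikoff 1994, position-based): at a column, a sequence
scores ``1 / (r * d)`` where ``r`` is the number of distinct characters in
the column and ``d`` the multiplicity of the sequence's own character; the
sequence weight is the average over columns.  Per-column scores sum to 1.

GSC94 (Gerstein, Sonnhammer & Chothia 1994, tree-based): visiting branches
from the tips to the root, each branch length is divided among its
descendant tips in proportion to their accumulated weights and added on.
Weights sum to the total branch length of the tree.
"""

from __future__ import annotations

import numpy as np

from .alignment import MISSING, Alignment
from .pns import WeightSet
from .tree import RootedPhylogeny


def hh94_weights(alignment: Alignment) -> WeightSet:
    """Position-based weights averaged over the alignment columns.

    Missing entries are excluded from both ``r`` and ``d`` and receive no
    score at that column (that sequence's averaging denominator shrinks);
    a sequence missing everywhere gets weight 0.
    """
    if alignment.n_columns == 0:
        raise ValueError("empty alignment")
    n = alignment.n_sequences
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    for k in range(alignment.n_columns):
        codes = alignment.codes[:, k]
        present = codes != MISSING
        if not present.any():
            continue
        vals, mult = np.unique(codes[present], return_counts=True)
        r = len(vals)
        d = dict(zip(vals.tolist(), mult.tolist()))
        for i in np.nonzero(present)[0]:
            sums[i] += 1.0 / (r * d[codes[i]])
            counts[i] += 1
    weights = {
        lab: float(sums[i] / counts[i]) if counts[i] else 0.0
        for i, lab in enumerate(alignment.labels)
    }
    return WeightSet("hh94", weights, metadata={"gap_policy": "excluded-from-r-and-d"})


def hh94_column_scores(alignment: Alignment, k: int) -> dict[str, float]:
    """Per-sequence scores ``1/(r d)`` for one column (missing rows omitted)."""
    codes = alignment.codes[:, k]
    present = codes != MISSING
    vals, mult = np.unique(codes[present], return_counts=True)
    r = len(vals)
    d = dict(zip(vals.tolist(), mult.tolist()))
    return {
        alignment.labels[i]: 1.0 / (r * d[codes[i]])
        for i in np.nonzero(present)[0]
    }


def gsc94_weights(tree: RootedPhylogeny) -> WeightSet:
    """Tree-based weights distributing branch lengths over descendant tips.

    Post-order over branches: pendant branches initialise each tip's
    weight; each internal branch's length is split among its descendant
    tips proportionally to their current weights, then added.  If all
    descendant weights are zero (an all-zero subtree) the split is equal,
    which keeps the weight total equal to the tree length.
    """
    w = np.zeros(tree.n_tips)
    tip_pos = {int(t): i for i, t in enumerate(tree.tip_ids)}
    desc: dict[int, list[int]] = {}
    for v in tree.postorder:
        v = int(v)
        if tree.is_tip(v):
            desc[v] = [tip_pos[v]]
            if v != tree.root:
                w[tip_pos[v]] = float(tree.blen[v])
        else:
            desc[v] = [i for c in tree.children[v] for i in desc[c]]
            if v == tree.root:
                continue
            t = float(tree.blen[v])
            idx = np.array(desc[v])
            cur = w[idx]
            total = cur.sum()
            if total > 0:
                w[idx] += t * cur / total
            else:
                w[idx] += t / len(idx)
    weights = {tree.labels[int(t)]: float(w[i]) for i, t in enumerate(tree.tip_ids)}
    return WeightSet("gsc94", weights)
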