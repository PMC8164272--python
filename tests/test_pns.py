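import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phylonovelty as pv
from phylonovelty.pns import ImpossibleDataError

from conftest import dist_map, random_column, random_reversible_model, two_tip_tree


class TestTwoTipClosedForms:
    """The analytically solvable two-tip JC case anchors the algorithm."""

    def test_half_pibd_tree(self, jc):
        ws = pv.pns_weights(two_tip_tree(np.log(2)), jc)
        assert ws.weights["A"] == pytest.approx(0.75, abs=1e-12)
        assert ws.weights["B"] == pytest.approx(0.75, abs=1e-12)
        assert ws.esn == pytest.approx(1.5, abs=1e-12)

    @given(
        t=st.floats(0.05, 5.0),
        split=st.floats(0.01, 0.99),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_weight_curve_independent_of_split(self, t, split):
        ws = pv.pns_weights(two_tip_tree(t, split), pv.jc69())
        assert ws.weights["A"] == pytest.approx(1 - np.exp(-t) / 2, abs=1e-9)
        assert ws.esn == pytest.approx(2 - np.exp(-t), abs=1e-9)

    def test_pibd_distribution_entries(self, jc):
        dists = pv.pibd_distributions(two_tip_tree(np.log(2)), jc)
        for d in dists:
            assert d.p[0] == 0.0
            assert d.p[1] == pytest.approx(0.5, abs=1e-12)
            assert d.p[2] == pytest.approx(0.5, abs=1e-12)


class TestDegenerateLimits:
    def test_zero_tree_gives_uniform_weights(self, jc):
        tree = pv.read_newick("((A:0,B:0):0,(C:0,(D:0,E:0):0):0);")
        ws = pv.pns_weights(tree, jc)
        for w in ws.weights.values():
            assert w == pytest.approx(1 / 5, abs=1e-12)
        assert ws.esn == pytest.approx(1.0, abs=1e-12)

    def test_saturated_tree_gives_unit_weights(self, hky):
        tree = pv.read_newick("((A:50,B:50):50,(C:50,D:50):50);")
        ws = pv.pns_weights(tree, hky)
        for w in ws.weights.values():
            assert w == pytest.approx(1.0, abs=1e-6)

    def test_single_tip(self, jc):
        tree_like = pv.read_newick("(A:0.5,B:0.5);")
        # two tips is the smallest supported tree; a 1-class column check:
        d = pv.pibd_distributions(tree_like, jc)[0]
        assert d.p.sum() == pytest.approx(1.0)


class TestConditionalWeights:
    def test_mismatching_characters_are_fully_novel(self, jc):
        tree = two_tip_tree(0.9)
        col = pv.AlignmentColumn.from_mapping({"A": "C", "B": "G"}, jc.states)
        ws = pv.conditional_pns_weights(tree, jc, col)
        assert ws.weights["A"] == pytest.approx(1.0, abs=1e-12)
        assert ws.weights["B"] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("t", [0.1, 0.7, 2.0])
    def test_matching_characters_closed_form(self, jc, t):
        col = pv.AlignmentColumn.from_mapping({"A": "T", "B": "T"}, jc.states)
        res = pv.updown(two_tip_tree(t), jc, col)
        p2 = 4 * np.exp(-t) / (1 + 3 * np.exp(-4 * t / 3))
        for d in res.distributions:
            assert d.p[2] == pytest.approx(p2, abs=1e-9)
            # w^D = 1 - p2/2, substituting the conditional PIBD probability
            assert d.weight == pytest.approx(1 - p2 / 2, abs=1e-9)

    def test_all_missing_column_equals_unconditional(self, hky):
        rng = np.random.default_rng(3)
        tree = pv.random_tree(6, rng)
        col = pv.empty_column(tree.tip_labels, hky.states)
        uncond = pv.pns_weights(tree, hky)
        cond = pv.conditional_pns_weights(tree, hky, col)
        for lab in tree.tip_labels:
            assert cond.weights[lab] == pytest.approx(uncond.weights[lab], abs=1e-10)

    def test_partially_missing_column_runs(self, jc):
        tree = pv.random_tree(5, np.random.default_rng(0))
        col = pv.AlignmentColumn.from_mapping(
            dict(zip(tree.tip_labels, ["A", None, "A", "C", None])), jc.states
        )
        ws = pv.conditional_pns_weights(tree, jc, col)
        assert all(0 < w <= 1 + 1e-12 for w in ws.weights.values())

    def test_impossible_column_raises(self):
        # a frozen model (all rates zero) cannot produce differing tips
        frozen = pv.custom_model(("A", "C"), Q=np.zeros((2, 2)),
                                 pi=(0.5, 0.5), normalise=False)
        tree = pv.read_newick("(A:1,B:1);")
        col = pv.AlignmentColumn(labels=("A", "B"), codes=np.array([0, 1]),
                                 states=("A", "C"))
        with pytest.raises(ImpossibleDataError):
            pv.updown(tree, frozen, col)

    def test_label_mismatch_raises(self, jc):
        tree = pv.read_newick("(A:1,B:1);")
        col = pv.AlignmentColumn.from_mapping({"A": "C", "X": "C"}, jc.states)
        with pytest.raises(KeyError):
            pv.updown(tree, jc, col)


class TestEsn:
    def test_two_tip_closed_form(self, jc):
        for t in (0.2, 1.0, 3.0):
            assert pv.esn(two_tip_tree(t), jc) == pytest.approx(
                2 - np.exp(-t), abs=1e-9
            )

    def test_pruning_recursion_matches_summed_weights(self, hky):
        rng = np.random.default_rng(11)
        tree = pv.random_tree(30, rng)
        assert pv.esn(tree, hky) == pytest.approx(
            pv.pns_weights(tree, hky).esn, abs=1e-9
        )

    def test_conditional_esn_equals_summed_conditional_weights(self, jc):
        tree = pv.random_tree(5, np.random.default_rng(4))
        col = random_column(tree, jc, np.random.default_rng(5))
        assert pv.esn(tree, jc, col) == pytest.approx(
            pv.conditional_pns_weights(tree, jc, col).esn, abs=1e-9
        )


class TestFastApproximation:
    def test_two_tip_value(self, jc):
        ws = pv.fast_pns_weights(two_tip_tree(np.log(2)), jc)
        assert ws.weights["A"] == pytest.approx(2 / 3, abs=1e-12)

    def test_degenerate_trees_match_exact(self, jc):
        zero = pv.read_newick("((A:0,B:0):0,C:0);")
        for w in pv.fast_pns_weights(zero, jc).weights.values():
            assert w == pytest.approx(1 / 3, abs=1e-12)
        sat = pv.read_newick("((A:60,B:60):60,C:60);")
        for w in pv.fast_pns_weights(sat, jc).weights.values():
            assert w == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n_states", [2, 4])
    def test_matches_pairwise_sum_oracle(self, n_states):
        rng = np.random.default_rng(21)
        model = random_reversible_model(rng, n_states)
        tree = pv.random_tree(12, rng)
        fast = pv.fast_pns_weights(tree, model)
        labels, D = tree.tip_distances()
        qd = np.diag(model.Q)
        for i, lab in enumerate(labels):
            expected_i = 1.0 + sum(
                model.pi @ np.exp(qd * D[i, j]) for j in range(len(labels)) if j != i
            )
            assert fast.weights[lab] == pytest.approx(1 / expected_i, abs=1e-10)

    def test_jensen_bound_against_exact(self, hky):
        rng = np.random.default_rng(8)
        for _ in range(5):
            tree = pv.random_tree(8, rng)
            exact = pv.pns_weights(tree, hky)
            fast = pv.fast_pns_weights(tree, hky)
            for lab in tree.tip_labels:
                assert fast.weights[lab] <= exact.weights[lab] + 1e-12


class TestStructuralInvariants:
    def test_root_placement_invariance(self, hky):
        # same unrooted 4-tip tree rooted three different ways
        a, b, c, d, f = 0.3, 0.6, 0.2, 0.9, 0.4
        rootings = [
            f"((A:{a},B:{b}):{f / 2},(C:{c},D:{d}):{f / 2});",
            f"(A:{a},B:{b},(C:{c},D:{d}):{f});",
            f"(A:{a * 0.3},(B:{b},(C:{c},D:{d}):{f}):{a * 0.7});",
        ]
        results = [pv.pns_weights(pv.read_newick(n), hky) for n in rootings]
        for other in results[1:]:
            for lab in "ABCD":
                assert other.weights[lab] == pytest.approx(
                    results[0].weights[lab], abs=1e-9
                )

    def test_multifurcation_resolution_invariance(self, jc):
        left = pv.read_newick("(A:1,B:1,C:1,D:1);")
        right = pv.read_newick("(D:1,C:1,B:1,A:1);")
        wl = pv.pns_weights(left, jc)
        wr = pv.pns_weights(right, jc)
        for lab in "ABCD":
            assert wl.weights[lab] == pytest.approx(wr.weights[lab], abs=1e-10)

    def test_weight_bounds(self):
        rng = np.random.default_rng(17)
        for model in (pv.jc69(), random_reversible_model(rng, 3)):
            tree = pv.random_tree(9, rng)
            ws = pv.pns_weights(tree, model)
            N = tree.n_tips
            for w in ws.weights.values():
                assert 1 / N - 1e-12 <= w <= 1 + 1e-12
            assert ws.esn == pytest.approx(sum(ws.weights.values()), abs=1e-9)

    def test_lengthening_pendant_branch_never_decreases_weight(self, jc):
        rng = np.random.default_rng(23)
        base = pv.random_tree(7, rng)
        lab = base.tip_labels[3]
        tip = base.tip_index[lab]
        previous = -np.inf
        for extra in (0.0, 0.2, 0.5, 1.5, 4.0):
            t = pv.read_newick(base.to_newick())
            t.blen[t.tip_index[lab]] = base.blen[tip] + extra
            w = pv.pns_weights(t, jc).weights[lab]
            assert w >= previous - 1e-12
            previous = w

    def test_distributions_are_normalised_with_zero_class_impossible(self, hky):
        rng = np.random.default_rng(31)
        tree = pv.random_tree(6, rng)
        for col in (None, random_column(tree, hky, rng)):
            for d in pv.pibd_distributions(tree, hky, col):
                assert d.p[0] == 0.0
                assert np.all(d.p >= -1e-15)
                assert d.p.sum() == pytest.approx(1.0, abs=1e-9)


class TestLikelihoodConsistency:
    def test_normaliser_equals_pruning_likelihood(self, hky):
        rng = np.random.default_rng(41)
        for _ in range(10):
            tree = pv.random_tree(int(rng.integers(2, 8)), rng)
            col = random_column(tree, hky, rng)
            res = pv.updown(tree, hky, col)
            assert res.likelihood == pytest.approx(
                pv.felsenstein_likelihood(tree, hky, col), abs=1e-9
            )

    def test_empty_column_likelihood_is_one(self, jc):
        tree = pv.random_tree(6, np.random.default_rng(2))
        assert pv.updown(tree, jc, None).likelihood == pytest.approx(1.0, abs=1e-9)


class TestAgainstBruteForce:
    @pytest.mark.parametrize("conditional", [False, True])
    def test_random_small_trees(self, conditional):
        rng = np.random.default_rng(99)
        for trial in range(15):
            n = int(rng.integers(2, 6))
            tree = pv.random_tree(n, rng)
            model = (
                pv.jc69() if trial % 3 == 0
                else pv.hky85(3.0, (0.3, 0.2, 0.2, 0.3)) if trial % 3 == 1
                else random_reversible_model(rng, 3)
            )
            col = random_column(tree, model, rng) if conditional else None
            exact = dist_map(pv.updown(tree, model, col))
            ref = dist_map(pv.brute_force_pibd(tree, model, col))
            for lab, d in exact.items():
                np.testing.assert_allclose(d.p, ref[lab].p, atol=1e-10)
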