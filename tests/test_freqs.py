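import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import dirichlet

import phylonovelty as pv
from phylonovelty.freqs import UndefinedEstimateError


def column(chars, states=("A", "C", "G", "T")):
    return pv.AlignmentColumn.from_mapping(
        {f"s{i}": c for i, c in enumerate(chars)}, states
    )


def weight_set(values):
    return pv.WeightSet("test", {f"s{i}": v for i, v in enumerate(values)})


class TestPointEstimates:
    def test_observed_frequencies(self):
        est = pv.observed_frequencies(column("AACT"))
        np.testing.assert_allclose(est.freqs, [0.5, 0.25, 0.0, 0.25])

    def test_all_same_character(self):
        np.testing.assert_allclose(
            pv.observed_frequencies(column("AAAA")).freqs, [1, 0, 0, 0]
        )

    def test_all_missing_raises(self):
        with pytest.raises(UndefinedEstimateError):
            pv.observed_frequencies(column([None, None]))

    def test_unit_weights_reduce_to_counts(self):
        col = column("ACGG")
        w = weight_set([1.0] * 4)
        np.testing.assert_allclose(
            pv.weighted_frequencies(col, w).freqs,
            pv.observed_frequencies(col).freqs,
        )

    def test_symmetric_weights(self):
        est = pv.weighted_frequencies(column("AC"), weight_set([0.75, 0.75]))
        np.testing.assert_allclose(est.freqs, [0.5, 0.5, 0, 0])

    def test_concentrated_weight(self):
        est = pv.weighted_frequencies(column("AC"), weight_set([1.0, 0.0]))
        np.testing.assert_allclose(est.freqs, [1, 0, 0, 0])

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            chars = rng.choice(list("ACGT") + [None], size=8)
            if all(c is None for c in chars):
                continue
            w = rng.uniform(0.1, 1.0, size=8)
            col = column(chars)
            est = pv.weighted_frequencies(col, weight_set(w))
            naive = np.zeros(4)
            tot = 0.0
            for i, c in enumerate(chars):
                if c is not None:
                    naive["ACGT".index(c)] += w[i]
                    tot += w[i]
            np.testing.assert_allclose(est.freqs, naive / tot, atol=1e-14)

    def test_zero_total_weight_raises(self):
        with pytest.raises(UndefinedEstimateError):
            pv.weighted_frequencies(column("AC"), weight_set([0.0, 0.0]))

    def test_missing_rows_drop_out(self):
        est = pv.weighted_frequencies(column(["A", None, "C"]),
                                      weight_set([1.0, 5.0, 1.0]))
        np.testing.assert_allclose(est.freqs, [0.5, 0.5, 0, 0])

    def test_invariant_to_weight_rescaling(self):
        col = column("ACGG")
        w = [0.3, 0.9, 0.5, 0.7]
        a = pv.weighted_frequencies(col, weight_set(w))
        b = pv.weighted_frequencies(col, weight_set([10 * x for x in w]))
        np.testing.assert_allclose(a.freqs, b.freqs, atol=1e-14)


class TestDirichletPosterior:
    def test_no_observations_gives_uniform_prior(self):
        post = pv.dirichlet_posterior(column([None, None]))
        np.testing.assert_allclose(post.alpha, 1.0)
        np.testing.assert_allclose(pv.posterior_mean(post).freqs, 0.25)

    def test_single_observation(self):
        post = pv.dirichlet_posterior(column(["A"]), weight_set([1.0]))
        np.testing.assert_allclose(post.alpha, [2, 1, 1, 1])
        np.testing.assert_allclose(pv.posterior_mean(post).freqs, [0.4, 0.2, 0.2, 0.2])

    def test_alpha_total_identity(self):
        rng = np.random.default_rng(2)
        w = rng.uniform(0, 1, size=6)
        post = pv.dirichlet_posterior(column("ACGTAC"), weight_set(w))
        assert post.alpha0 - post.B == pytest.approx(w.sum())

    def test_posterior_not_invariant_to_weight_rescaling(self):
        col = column("ACGG")
        w = [0.3, 0.9, 0.5, 0.7]
        a = pv.dirichlet_posterior(col, weight_set(w))
        b = pv.dirichlet_posterior(col, weight_set([10 * x for x in w]))
        assert a.alpha0 != pytest.approx(b.alpha0)

    def test_prior_only_variance(self):
        post = pv.dirichlet_posterior(column([None]))
        np.testing.assert_allclose(pv.posterior_variance(post), 3 / 80)

    def test_moments_match_scipy_dirichlet(self):
        rng = np.random.default_rng(9)
        w = rng.uniform(0.2, 2.0, size=7)
        post = pv.dirichlet_posterior(column("ACGGTTA"), weight_set(w))
        ref = dirichlet(post.alpha)
        np.testing.assert_allclose(pv.posterior_mean(post).freqs, ref.mean())
        np.testing.assert_allclose(pv.posterior_variance(post), ref.var())

    def test_variance_matches_monte_carlo(self):
        rng = np.random.default_rng(12)
        alpha = np.array([2.0, 1.3, 1.0, 4.0])
        post = pv.DirichletPosterior(alpha, ("A", "C", "G", "T"))
        draws = rng.dirichlet(alpha, size=100_000)
        mc_var = draws.var(axis=0)
        se = draws.var(axis=0) * np.sqrt(2 / 100_000) * 3  # rough 3 SE band
        assert np.all(np.abs(pv.posterior_variance(post) - mc_var) < se + 1e-4)

    def test_map_equals_weighted_frequencies(self):
        # numeric maximisation of the Dirichlet log-density over the simplex
        rng = np.random.default_rng(33)
        chars = "ACGGTA"
        w = rng.uniform(0.3, 1.5, size=6)
        col = column(chars)
        post = pv.dirichlet_posterior(col, weight_set(w))
        pw = pv.weighted_frequencies(col, weight_set(w)).freqs

        def neg_logpost(z):
            p = np.exp(z) / np.exp(z).sum()
            return -np.sum((post.alpha - 1) * np.log(np.maximum(p, 1e-12)))

        opt = minimize(neg_logpost, np.zeros(4), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        p_hat = np.exp(opt.x) / np.exp(opt.x).sum()
        np.testing.assert_allclose(p_hat, pw, atol=1e-4)

    def test_mean_equals_weighted_freqs_with_pseudocounts(self):
        # algebraic identity: adding one unit-weight row per state turns
        # the weighted frequency into the posterior mean
        chars = ["A", "C", "C"]
        w = [0.5, 0.25, 0.75]
        col = column(chars)
        post = pv.dirichlet_posterior(col, weight_set(w))
        aug_map = {f"s{i}": c for i, c in enumerate(chars)}
        aug_w = {f"s{i}": v for i, v in enumerate(w)}
        for j, s in enumerate("ACGT"):
            aug_map[f"pseudo{j}"] = s
            aug_w[f"pseudo{j}"] = 1.0
        aug_col = pv.AlignmentColumn.from_mapping(aug_map, ("A", "C", "G", "T"))
        aug = pv.weighted_frequencies(aug_col, pv.WeightSet("aug", aug_w))
        np.testing.assert_allclose(pv.posterior_mean(post).freqs, aug.freqs, atol=1e-14)


class TestCredibleIntervals:
    def test_symmetric_prior_interval(self):
        post = pv.DirichletPosterior(np.array([1.0, 1.0]), ("A", "C"))
        lo, hi = pv.credible_interval(post, "A", 0.95)
        assert lo == pytest.approx(1 - hi, abs=1e-12)

    def test_interval_brackets_mean(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(0.2, 1.5, size=9)
        post = pv.dirichlet_posterior(column("ACGGTACGT"), weight_set(w))
        mean = pv.posterior_mean(post)
        for s in "ACGT":
            lo, hi = pv.credible_interval(post, s, 0.95)
            assert lo <= mean[s] <= hi

    def test_bad_level_raises(self):
        post = pv.DirichletPosterior(np.ones(4), ("A", "C", "G", "T"))
        with pytest.raises(ValueError):
            pv.credible_interval(post, "A", 1.5)


class TestConservationScore:
    def test_uniform_frequencies_score_zero(self):
        est = pv.FrequencyEstimate(np.full(4, 0.25), ("A", "C", "G", "T"), "counts")
        assert pv.conservation_score(est).R == pytest.approx(0.0, abs=1e-12)

    def test_fixed_nucleotide_scores_two_bits(self):
        est = pv.FrequencyEstimate(np.array([1, 0, 0, 0.0]), ("A", "C", "G", "T"), "counts")
        assert pv.conservation_score(est).R == pytest.approx(2.0)

    def test_fixed_amino_acid_scores_log2_20(self):
        p = np.zeros(20)
        p[0] = 1.0
        est = pv.FrequencyEstimate(p, tuple(pv.models.AMINO_ACIDS), "counts")
        assert pv.conservation_score(est).R == pytest.approx(np.log2(20))

    def test_score_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.dirichlet(np.full(4, 0.3))
            est = pv.FrequencyEstimate(p, ("A", "C", "G", "T"), "counts")
            r = pv.conservation_score(est).R
            assert -1e-12 <= r <= 2.0 + 1e-12
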