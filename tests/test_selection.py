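import numpy as np
import pytest
from scipy.special import comb

import expevo as ev
from expevo.data import GeneObservations
from expevo.engine import McmcSettings, PosteriorTrace
from expevo.models import GeneStats, Model, ModelParams, ModelSpec
from expevo.selection import (
    branch_shift_probability_batch,
    classify_shift_direction,
    conserved_gene_test,
    conserved_test_budget,
    phylo_signal_batch,
    sign_test,
    variance_shift_comparison,
)


def _simulate_batch(spec, params_fn, tree, reps, n, rng):
    stats = [GeneStats.from_gene(
        ev.simulate_gene(spec, params_fn(), tree, reps, rng), tree.tips)
        for _ in range(n)]
    return GeneStats.stack(stats)


@pytest.fixture(scope="module")
def sel_settings():
    return McmcSettings(burnin=100, iterations=300, thinning=5, seed=17)


class TestPhyloSignal:
    """Model recovery on genes simulated under each competing regime."""

    N = 25

    def test_bm_genes_support_bm_over_unequal_means(self, tree,
                                                    sel_settings, rng):
        d2 = {sp: 0.3 for sp in tree.tips}
        stats = _simulate_batch(
            ModelSpec(Model.BM),
            lambda: ModelParams(sigma2=1.0, delta2=d2, root=5.0),
            tree, {sp: 8 for sp in tree.tips}, self.N, rng)
        res = phylo_signal_batch(tree, stats, settings=sel_settings,
                                 stones=12)
        assert (res["p_BM_vs_UNEQUAL_MEANS"] > 0.75).sum() > self.N / 2

    def test_equal_mean_genes_favor_equal_over_unequal(self, tree,
                                                       sel_settings, rng):
        d2 = {sp: 0.3 for sp in tree.tips}
        stats = _simulate_batch(
            ModelSpec(Model.EQUAL_MEANS),
            lambda: ModelParams(mu=5.0, delta2=d2),
            tree, {sp: 8 for sp in tree.tips}, self.N, rng)
        res = phylo_signal_batch(tree, stats, settings=sel_settings,
                                 stones=12)
        assert (res["p_UNEQUAL_vs_EQUAL_MEANS"] < 0.5).sum() > self.N / 2

    def test_star_like_means_weaken_bm_support(self, tree,
                                               sel_settings, rng):
        """Species means far apart with anti-phylogenetic structure.

        Under the study's wide mean priors the five-free-means model pays a
        ~26-nat Occam cost, so REML-BM still wins in absolute terms even on
        structureless data (mirroring the near-universal phylogenetic signal
        the method reports); the check here is that the BM-vs-UNEQUAL Bayes
        factor responds in the right direction, and that such genes clearly
        reject the identical-means model.
        """
        d2 = {sp: 0.3 for sp in tree.tips}
        base = {"sara": 0.0, "charithonia": 8.0, "doris": 8.0,
                "melpomene": 0.0, "erato": 4.0}
        star = _simulate_batch(
            ModelSpec(Model.UNEQUAL_MEANS),
            lambda: ModelParams(
                mu_i={sp: base[sp] + rng.normal(0, 0.5)
                      for sp in tree.tips}, delta2=d2),
            tree, {sp: 8 for sp in tree.tips}, self.N, rng)
        bm = _simulate_batch(
            ModelSpec(Model.BM),
            lambda: ModelParams(sigma2=1.0, delta2=d2, root=5.0),
            tree, {sp: 8 for sp in tree.tips}, self.N, rng)
        rs = phylo_signal_batch(tree, star, settings=sel_settings, stones=12)
        rb = phylo_signal_batch(tree, bm, settings=sel_settings, stones=12)
        lbf_star = rs["logml_BM"] - rs["logml_UNEQUAL_MEANS"]
        lbf_bm = rb["logml_BM"] - rb["logml_UNEQUAL_MEANS"]
        assert lbf_star.mean() < lbf_bm.mean()
        assert (rs["p_UNEQUAL_vs_EQUAL_MEANS"] > 0.75).sum() > self.N / 2


class TestConservedGeneTest:
    def test_budget_accounting(self):
        assert conserved_test_budget(2393, 1000) == 2_395_393

    def test_minimum_simulations_enforced(self, tree):
        gene = GeneObservations(
            "g", {sp: np.array([1.0, 2.0]) for sp in tree.tips})
        with pytest.raises(ValueError, match="at least 100"):
            conserved_gene_test(gene, tree, n_sim=50)

    def test_conserved_gene_flagged(self, tree, rng):
        """A sigma^2 = 0 gene should usually pass the conserved test."""
        d2 = {sp: float(np.exp(rng.normal(np.log(0.2), 0.5)))
              for sp in tree.tips}
        gene = ev.simulate_gene(ModelSpec(Model.EQUAL_MEANS),
                                ModelParams(mu=5.0, delta2=d2),
                                tree, {sp: 8 for sp in tree.tips}, rng)
        st = McmcSettings(burnin=150, iterations=500, thinning=10, seed=23)
        res = conserved_gene_test(gene, tree, settings=st, n_sim=100,
                                  keep_simulated=True)
        assert res.conserved is (res.empirical_mean_sigma2
                                 <= res.threshold_95)
        assert res.simulated_means.shape == (100,)

    def test_fast_evolving_gene_not_conserved(self, tree, rng):
        d2 = {sp: 0.2 for sp in tree.tips}
        gene = ev.simulate_gene(ModelSpec(Model.BM),
                                ModelParams(sigma2=5.0, delta2=d2, root=5.0),
                                tree, {sp: 8 for sp in tree.tips}, rng)
        st = McmcSettings(burnin=150, iterations=500, thinning=10, seed=29)
        res = conserved_gene_test(gene, tree, settings=st, n_sim=100)
        assert not res.conserved


class TestBranchShift:
    def test_ou_optimum_shift_detected_with_down_direction(self, tree, rng):
        """OU optimum shift of -3: detected for most genes, direction down."""
        d2 = {sp: 0.3 for sp in tree.tips}
        st = McmcSettings(burnin=100, iterations=400, thinning=5, seed=31)
        results = []
        for _ in range(6):
            gene = ev.simulate_gene(
                ModelSpec(Model.OU_SHIFT, "doris"),
                ModelParams(sigma2_B=0.2, sigma2_F=0.2, alpha=0.5,
                            theta_B=5.0, theta_F=2.0, delta2=d2),
                tree, {sp: 8 for sp in tree.tips}, rng)
            results.append(ev.branch_shift_test(gene, tree, "doris",
                                                family="OU", settings=st,
                                                stones=16))
        assert sum(r.probability > 0.75 for r in results) >= 4
        for r in results:
            if r.significant:
                assert r.direction == "down" and not r.tie
            else:
                assert r.direction is None

    def test_internal_branch_foreground_rejected(self, tree):
        gene = GeneObservations(
            "g", {sp: np.array([1.0, 2.0]) for sp in tree.tips})
        with pytest.raises(ValueError, match="tip branch"):
            ev.branch_shift_test(gene, tree, "n1", family="BM")

    def test_label_equivariance(self, tree, sel_settings, rng):
        """Swapping two species' data swaps which tip carries the shift."""
        d2 = {sp: 0.3 for sp in tree.tips}
        gene = ev.simulate_gene(
            ModelSpec(Model.OU_SHIFT, "doris"),
            ModelParams(sigma2_B=0.2, sigma2_F=0.2, alpha=0.5,
                        theta_B=5.0, theta_F=1.0, delta2=d2),
            tree, {sp: 8 for sp in tree.tips}, rng)
        # doris and melpomene are sisters with equal branch lengths, so the
        # tree is invariant under their exchange
        swapped = GeneObservations("g", dict(gene.values))
        swapped.values["doris"], swapped.values["melpomene"] = \
            gene.values["melpomene"], gene.values["doris"]
        s1 = GeneStats.from_gene(gene, tree.tips)
        s2 = GeneStats.from_gene(swapped, tree.tips)
        p1, _, _ = branch_shift_probability_batch(
            tree, s1, "doris", "OU", settings=sel_settings, stones=12)
        p2, _, _ = branch_shift_probability_batch(
            tree, s2, "melpomene", "OU", settings=sel_settings, stones=12)
        assert abs(p1[0] - p2[0]) < 0.25  # same decision, MC noise aside
        assert (p1[0] > 0.75) == (p2[0] > 0.75)


class TestDirectionCall:
    def test_bm_direction_from_sample_means(self):
        gene = GeneObservations("g", {
            "fg": np.array([2.0, 2.0]),
            "b1": np.array([5.0, 5.0]), "b2": np.array([5.2, 5.2]),
            "b3": np.array([4.8, 4.8]), "b4": np.array([5.1, 5.1])})
        direction, tie = classify_shift_direction(gene, "fg", "BM")
        assert direction == "down" and not tie

    def test_ou_direction_from_theta_posterior(self):
        trace = PosteriorTrace(
            names=["theta_B", "theta_F"], iteration=np.arange(2),
            samples=np.array([[1.0, 6.0], [1.0, 6.0]]),
            loglik=np.zeros(2), acceptance={}, scales={})
        gene = GeneObservations("g", {"a": [0.0, 0.0]})
        direction, tie = classify_shift_direction(gene, "a", "OU", trace)
        assert direction == "up" and not tie

    def test_exact_tie_breaks_down_with_flag(self):
        gene = GeneObservations("g", {
            "fg": np.array([5.0, 5.0]), "b1": np.array([5.0, 5.0]),
            "b2": np.array([5.0, 5.0])})
        direction, tie = classify_shift_direction(gene, "fg", "BM")
        assert direction == "down" and tie


class TestShiftTables:
    def _results(self):
        from expevo.selection import ShiftResult

        mk = lambda g, fg, fam, p, sig, d: ShiftResult(  # noqa: E731
            gene=g, foreground=fg, family=fam, probability=p,
            log_marginal_shift=-1.0, log_marginal_null=-2.0,
            significant=sig, direction=d)
        return [mk("g1", "erato", "BM", 0.9, True, "up"),
                mk("g2", "erato", "BM", 0.8, True, "down"),
                mk("g3", "sara", "OU", 0.97, True, "down"),
                mk("g4", "sara", "BM", 0.4, False, None)]

    def test_per_gene_table(self):
        from expevo.selection import shift_results_table

        df = shift_results_table(self._results())
        assert len(df) == 4
        assert df.significant.sum() == 3

    def test_summary_counts_by_species_family_direction(self):
        from expevo.selection import shift_summary

        s = shift_summary(self._results()).set_index(
            ["foreground", "family", "direction"])
        assert s.loc[("erato", "BM", "up"), "n_genes"] == 1
        assert s.loc[("sara", "OU", "down"), "n_genes"] == 1
        assert s.n_genes.sum() == 3


class TestSignTest:
    def test_balanced_counts(self):
        assert sign_test(3, 3) == pytest.approx(1.0)

    def test_one_sided_extreme(self):
        assert sign_test(0, 6) == pytest.approx(2 * 0.5 ** 6)

    def test_matches_binomial_tail_enumeration(self):
        n_up, n_down = 10, 30
        n = n_up + n_down
        pk = np.array([comb(n, k) * 0.5 ** n for k in range(n + 1)])
        brute = pk[pk <= pk[n_up] * (1 + 1e-12)].sum()
        assert sign_test(n_up, n_down) == pytest.approx(brute, rel=1e-9)

    def test_symmetry(self):
        assert sign_test(4, 11) == pytest.approx(sign_test(11, 4))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sign_test(0, 0)


class TestVarianceShiftComparison:
    def test_identical_sets(self):
        p = variance_shift_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_fully_separated_small_sets_exact(self):
        # all 3 ranks below all 3: 2 / C(6,3) * ... = two-sided exact 0.1
        assert variance_shift_comparison([1, 2, 3], [10, 11, 12]) == \
            pytest.approx(0.1)

    def test_scaled_variances_strongly_significant(self, rng):
        hits = 0
        for _ in range(5):
            up = rng.exponential(1.0, size=50)
            down = rng.exponential(4.0, size=50)
            hits += variance_shift_comparison(up, down) < 1e-3
        assert hits >= 3

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            variance_shift_comparison([], [1.0])
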