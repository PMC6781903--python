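import numpy as np
import pytest
from scipy.integrate import quad

import expevo as ev
from expevo.data import GeneObservations
from expevo.models import Model, ModelParams, ModelSpec

from oracles import (
    all_model_specs,
    bm_covariance_by_path_enumeration,
    dense_mvn_loglik,
    random_params,
)


class TestBmCovariance:
    def test_two_tips_no_shared_path(self):
        t = ev.parse_newick("(A:1,B:1):0;")
        np.testing.assert_allclose(ev.bm_tip_covariance(t, 1.0),
                                   np.eye(2))

    def test_three_taxon_shared_path(self):
        t = ev.parse_newick("((A:1,B:1):1,C:2):0;")
        V = ev.bm_tip_covariance(t, 2.0)
        tips = t.tips
        a, b, c = tips.index("A"), tips.index("B"), tips.index("C")
        assert V[a, b] == pytest.approx(2.0)
        assert V[a, a] == V[b, b] == V[c, c] == pytest.approx(4.0)
        assert V[a, c] == 0.0

    def test_matches_path_enumeration_oracle(self, tree, rng):
        rates = {k: float(np.exp(rng.normal())) for k in tree.edge_keys}
        V = ev.bm_tip_covariance(tree, rates)
        np.testing.assert_allclose(
            V, bm_covariance_by_path_enumeration(tree, rates), rtol=1e-12)
        # symmetric positive semi-definite
        np.testing.assert_allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > -1e-9

    def test_missing_edge_rate_is_error(self, tree):
        with pytest.raises(ValueError, match="no rate"):
            ev.bm_tip_covariance(tree, {"erato": 1.0})


class TestOuMoments:
    def test_stationary_variance(self, tree):
        _, cov = ev.ou_tip_moments(tree, sigma2=2.0, alpha=1.0, theta=0.0)
        np.testing.assert_allclose(np.diag(cov), 1.0)  # sigma2 / (2 alpha)

    def test_bm_limit_on_difference_variances(self, tree):
        """As alpha -> 0 the translation-invariant part of the OU covariance
        converges to BM: Var(x_i - x_j) matches entrywise."""
        s2 = 2.0
        _, cov = ev.ou_tip_moments(tree, s2, alpha=1e-8, theta=0.0)
        Vbm = ev.bm_tip_covariance(tree, s2)
        d_ou = np.add.outer(np.diag(cov), np.diag(cov)) - 2 * cov
        d_bm = np.add.outer(np.diag(Vbm), np.diag(Vbm)) - 2 * Vbm
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(d_ou[off], d_bm[off], rtol=1e-5)

    def test_tiny_alpha_rejected(self, tree):
        with pytest.raises(ValueError, match="BM limit"):
            ev.ou_tip_moments(tree, 1.0, alpha=1e-13, theta=0.0)

    def test_against_euler_maruyama_simulation(self):
        """3-taxon covariance vs 200k discretized OU paths (3 SE)."""
        t = ev.parse_newick("((A:1,B:1):1,C:2):0;")
        s2, alpha, theta = 1.0, 0.5, 1.5
        mean, cov = ev.ou_tip_moments(t, s2, alpha, theta)
        rng = np.random.default_rng(99)
        n, dt = 200_000, 0.005
        sd = np.sqrt(s2 * dt)

        def evolve(x0, time):
            x = x0.copy()
            for _ in range(int(round(time / dt))):
                x += alpha * (theta - x) * dt + sd * rng.standard_normal(n)
            return x

        root = rng.normal(theta, np.sqrt(s2 / (2 * alpha)), size=n)
        node_ab = evolve(root, 1.0)
        xa, xb = evolve(node_ab, 1.0), evolve(node_ab, 1.0)
        xc = evolve(root, 2.0)
        sims = {"A": xa, "B": xb, "C": xc}
        tips = t.tips
        for i, ti in enumerate(tips):
            se = np.sqrt(2.0 / (n - 1)) * cov[i, i]
            assert abs(np.var(sims[ti]) - cov[i, i]) < 3 * se + 0.01
            assert abs(np.mean(sims[ti]) - mean[i]) < 0.02
        i, j = tips.index("A"), tips.index("B")
        c_hat = np.cov(sims["A"], sims["B"])[0, 1]
        assert abs(c_hat - cov[i, j]) < 0.02


class TestModelLoglik:
    def test_standard_normal_at_its_mean(self):
        t = ev.parse_newick("(A:1,B:1):0;", require_ultrametric=False)
        # one-replicate species: within-species terms vanish
        gene = GeneObservations("g", {"A": [0.0], "B": [0.0]})
        spec = ModelSpec(Model.EQUAL_MEANS)
        params = ModelParams(mu=0.0, delta2={"A": 1.0, "B": 1.0})
        ll = ev.model_loglik(spec, params, gene, t)
        assert ll == pytest.approx(2 * (-0.5 * np.log(2 * np.pi)))

    def test_reml_translation_invariance(self, tree, rng):
        d2 = {sp: 0.4 for sp in tree.tips}
        gene = ev.simulate_gene(ModelSpec(Model.BM),
                                ModelParams(sigma2=1.0, delta2=d2, root=3.0),
                                tree, {sp: 4 for sp in tree.tips}, rng)
        shifted = GeneObservations(
            "g", {sp: v + 7.3 for sp, v in gene.values.items()})
        spec = ModelSpec(Model.BM)
        params = ModelParams(sigma2=0.5, delta2=d2)
        assert ev.model_loglik(spec, params, gene, tree) == pytest.approx(
            ev.model_loglik(spec, params, shifted, tree), abs=1e-9)

    @pytest.mark.parametrize("spec", all_model_specs(),
                             ids=lambda s: s.model.value)
    def test_matches_dense_mvn_oracle(self, spec, tree, rng):
        reps = {sp: 3 for sp in tree.tips}
        for _ in range(10):
            params = random_params(spec, tree.tips, rng)
            gene = ev.simulate_gene(spec, random_params(spec, tree.tips, rng),
                                    tree, reps, rng)
            assert ev.model_loglik(spec, params, gene, tree) == pytest.approx(
                dense_mvn_loglik(spec, params, gene, tree), abs=1e-8)

    @pytest.mark.parametrize("model", [Model.EQUAL_MEANS, Model.OU],
                             ids=lambda m: m.value)
    def test_density_normalized_one_species_one_replicate(self, model):
        """exp(loglik) integrates to 1 over the single observation."""
        t = ev.parse_newick("(A:1,B:1):0;", require_ultrametric=False)
        d2 = {"A": 0.7, "B": 0.7}
        if model is Model.EQUAL_MEANS:
            spec, params = ModelSpec(model), ModelParams(mu=0.3, delta2=d2)
        else:
            spec = ModelSpec(model)
            params = ModelParams(sigma2=1.2, alpha=0.8, theta=0.3, delta2=d2)

        def dens(x):
            g = GeneObservations("g", {"A": [x], "B": [0.1]})
            return np.exp(ev.model_loglik(spec, params, g, t))

        marginal = quad(lambda x: dens(x), -30, 30, limit=200)[0]
        norm = quad(lambda x: dens(x) / marginal * 0 + 1, 0, 1)[0]  # sanity
        # conditional density of A's observation integrates to the marginal
        # density of B's observation
        gB_only_var = (params.delta2["B"]
                       + (0 if model is Model.EQUAL_MEANS
                          else params.sigma2 / (2 * params.alpha)))
        from scipy.stats import norm as normal
        expected = normal(params.mu if model is Model.EQUAL_MEANS
                          else params.theta,
                          np.sqrt(gB_only_var)).pdf(0.1)
        assert marginal == pytest.approx(expected, rel=1e-6)
        assert norm == pytest.approx(1.0)

    def test_shift_models_reduce_to_their_base_models(self, tree, rng):
        d2 = {sp: 0.4 for sp in tree.tips}
        gene = ev.simulate_gene(
            ModelSpec(Model.BM), ModelParams(sigma2=1.0, delta2=d2, root=2.0),
            tree, {sp: 4 for sp in tree.tips}, rng)
        bm = ev.model_loglik(ModelSpec(Model.BM),
                             ModelParams(sigma2=0.7, delta2=d2), gene, tree)
        bms = ev.model_loglik(
            ModelSpec(Model.BM_SHIFT, "sara"),
            ModelParams(sigma2_B=0.7, sigma2_F=0.7, delta2=d2), gene, tree)
        assert bms == pytest.approx(bm, abs=1e-10)
        ou = ev.model_loglik(
            ModelSpec(Model.OU),
            ModelParams(sigma2=0.7, alpha=0.3, theta=2.0, delta2=d2),
            gene, tree)
        ous = ev.model_loglik(
            ModelSpec(Model.OU_SHIFT, "sara"),
            ModelParams(sigma2_B=0.7, sigma2_F=0.7, alpha=0.3,
                        theta_B=2.0, theta_F=2.0, delta2=d2), gene, tree)
        assert ous == pytest.approx(ou, abs=1e-10)

    def test_params_must_match_spec(self, tree):
        d2 = {sp: 1.0 for sp in tree.tips}
        with pytest.raises(ValueError, match="requires sigma2"):
            ModelParams(mu=0.0, delta2=d2).validate(ModelSpec(Model.BM),
                                                    tree.tips)
        with pytest.raises(ValueError, match="does not use"):
            ModelParams(sigma2=1.0, alpha=1.0, delta2=d2).validate(
                ModelSpec(Model.BM), tree.tips)


class TestSimulateGene:
    def test_zero_rate_bm_keeps_root_state(self, tree, rng):
        params = ModelParams(sigma2=0.0, root=4.0,
                             delta2={sp: 0.0 for sp in tree.tips})
        g = ev.simulate_gene(ModelSpec(Model.BM), params, tree,
                             {sp: 3 for sp in tree.tips}, rng)
        for sp in tree.tips:
            np.testing.assert_allclose(g.values[sp], 4.0)

    def test_bm_divergence_law_two_tips(self):
        """Var(mean_A - mean_B) ~ 2 sigma^2 T on (A:4,B:4)."""
        t = ev.parse_newick("(A:4,B:4):0;")
        rng = np.random.default_rng(5)
        params = ModelParams(sigma2=1.0, delta2={"A": 0.0, "B": 0.0})
        diffs = np.empty(10_000)
        for i in range(10_000):
            g = ev.simulate_gene(ModelSpec(Model.BM), params, t,
                                 {"A": 1, "B": 1}, rng)
            diffs[i] = g.values["A"][0] - g.values["B"][0]
        se = 8.0 * np.sqrt(2.0 / (len(diffs) - 1))
        assert abs(np.var(diffs) - 8.0) < 3 * se

    def test_ou_tip_variance_independent_of_depth(self, rng):
        """Large alpha * depth: tip variance ~ sigma2/(2 alpha) whatever T."""
        out = []
        for depth in (2.0, 20.0):
            t = ev.parse_newick(f"(A:{depth},B:{depth}):0;")
            params = ModelParams(sigma2=2.0, alpha=1.0, theta=0.0,
                                 delta2={"A": 0.0, "B": 0.0})
            vals = [ev.simulate_gene(ModelSpec(Model.OU), params, t,
                                     {"A": 1, "B": 1}, rng).values["A"][0]
                    for _ in range(4000)]
            out.append(np.var(vals))
        se = 1.0 * np.sqrt(2.0 / 3999)
        assert abs(out[0] - 1.0) < 3 * se
        assert abs(out[1] - 1.0) < 3 * se

    def test_reproducible_under_fixed_seed(self, tree):
        params = ModelParams(sigma2=1.0, root=2.0,
                             delta2={sp: 0.3 for sp in tree.tips})
        g1 = ev.simulate_gene(ModelSpec(Model.BM), params, tree,
                              {sp: 5 for sp in tree.tips}, seed=42)
        g2 = ev.simulate_gene(ModelSpec(Model.BM), params, tree,
                              {sp: 5 for sp in tree.tips}, seed=42)
        for sp in tree.tips:
            np.testing.assert_array_equal(g1.values[sp], g2.values[sp])

    def test_zero_replicates_is_error(self, tree):
        params = ModelParams(sigma2=1.0,
                             delta2={sp: 0.3 for sp in tree.tips})
        with pytest.raises(ValueError, match="replicate count"):
            ev.simulate_gene(ModelSpec(Model.BM), params, tree,
                             {sp: 0 for sp in tree.tips}, seed=1)

    def test_loglik_peaks_near_generating_parameters(self, tree, rng):
        """Average log likelihood at the truth beats a perturbed value
        across 500 simulated genes (simulation/likelihood consistency)."""
        from expevo.models import GeneStats, TreeCache, loglik_batch

        d2 = {sp: 0.3 for sp in tree.tips}
        spec = ModelSpec(Model.BM)
        true = ModelParams(sigma2=1.0, delta2=d2, root=0.0)
        stats = GeneStats.stack([
            GeneStats.from_gene(
                ev.simulate_gene(spec, true, tree,
                                 {sp: 5 for sp in tree.tips}, rng),
                tree.tips)
            for _ in range(500)])
        cache = TreeCache(tree)

        def mean_ll(sigma2):
            x = np.column_stack([np.full(500, sigma2)]
                                + [np.full(500, 0.3)] * 5)
            return loglik_batch(spec, cache, stats, x).mean()

        assert mean_ll(1.0) > mean_ll(5.0)
        assert mean_ll(1.0) > mean_ll(0.2)
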