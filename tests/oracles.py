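"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's likelihood code paths: the dense MVN
oracle expands the phylogenetic covariance to the per-individual level and
evaluates scipy's multivariate normal directly (through an orthonormal
contrast basis for the REML models), and the path-sum oracle accumulates
per-edge rate x length terms over explicitly enumerated root-to-tip paths.
"""

import numpy as np
from scipy.stats import multivariate_normal

import expevo as ev
from expevo.models import Model, ModelParams, ModelSpec


def bm_covariance_by_path_enumeration(tree, rates):
    """Shared-path covariance via explicit root-to-tip edge sets."""
    tips = tree.tips
    paths = {lab: set(tree.path_edges(lab)) for lab in tips}
    out = np.zeros((len(tips), len(tips)))
    for a, la in enumerate(tips):
        for b, lb in enumerate(tips):
            shared = paths[la] & paths[lb]
            out[a, b] = sum(rates[tree.node_keys[i]] * tree.blen[i]
                            for i in shared)
    return out


def species_mean_moments(spec, params, tree):
    """Mean vector and covariance of latent species means for any model."""
    tips = tree.tips
    S = len(tips)
    m = spec.model
    if m is Model.EQUAL_MEANS:
        return np.full(S, params.mu), np.zeros((S, S))
    if m is Model.UNEQUAL_MEANS:
        return np.array([params.mu_i[sp] for sp in tips]), np.zeros((S, S))
    if m is Model.BM:
        return np.zeros(S), ev.bm_tip_covariance(tree, params.sigma2)
    if m is Model.BM_SHIFT:
        rates = {k: params.sigma2_B for k in tree.node_keys[1:]}
        rates[spec.foreground] = params.sigma2_F
        return np.zeros(S), ev.bm_tip_covariance(tree, rates)
    if m is Model.OU:
        return ev.ou_tip_moments(tree, params.sigma2, params.alpha,
                                 params.theta)
    return ev.ou_tip_moments(
        tree, params.sigma2_B, params.alpha,
        {spec.foreground: params.theta_F},
        sigma2_map={spec.foreground: params.sigma2_F},
        root_theta=params.theta_B)


def dense_mvn_loglik(spec, params, gene, tree):
    """Gene log likelihood from the full per-individual covariance matrix.

    Expands the species-level phylogenetic covariance to individuals, adds
    diagonal within-species variance, and evaluates the joint MVN density --
    through an orthonormal basis of contrasts (orthogonal to the all-ones
    vector) for the REML-treated BM-family models.
    """
    tips = tree.tips
    mean_s, V = species_mean_moments(spec, params, tree)
    ns = [len(gene.values[sp]) for sp in tips]
    N = sum(ns)
    Z = np.zeros((N, len(tips)))
    k = 0
    for j, nj in enumerate(ns):
        Z[k:k + nj, j] = 1.0
        k += nj
    d2 = np.concatenate([[params.delta2[sp]] * nj
                         for sp, nj in zip(tips, ns)])
    sigma = Z @ V @ Z.T + np.diag(d2)
    y = np.concatenate([gene.values[sp] for sp in tips])
    mu = Z @ mean_s
    if spec.model in (Model.BM, Model.BM_SHIFT):
        q, _ = np.linalg.qr(np.column_stack(
            [np.ones(N) / np.sqrt(N), np.eye(N)[:, : N - 1]]))
        c = q[:, 1:].T  # (N-1, N), orthonormal, rows orthogonal to 1
        return multivariate_normal(c @ mu, c @ sigma @ c.T).logpdf(c @ y)
    return multivariate_normal(mu, sigma).logpdf(y)


def random_params(spec, species, rng):
    """A random valid parameter block for a model, for oracle sweeps."""
    d2 = {sp: float(np.exp(rng.uniform(-2.0, 1.0))) for sp in species}
    m = spec.model
    if m is Model.EQUAL_MEANS:
        return ModelParams(mu=rng.uniform(-5, 5), delta2=d2)
    if m is Model.UNEQUAL_MEANS:
        return ModelParams(mu_i={sp: rng.uniform(-5, 5) for sp in species},
                           delta2=d2)
    if m is Model.BM:
        return ModelParams(sigma2=np.exp(rng.uniform(-3, 1)), delta2=d2)
    if m is Model.BM_SHIFT:
        return ModelParams(sigma2_B=np.exp(rng.uniform(-3, 1)),
                           sigma2_F=np.exp(rng.uniform(-3, 1)), delta2=d2)
    if m is Model.OU:
        return ModelParams(sigma2=np.exp(rng.uniform(-3, 1)),
                           alpha=np.exp(rng.uniform(-3, 1)),
                           theta=rng.uniform(-5, 5), delta2=d2)
    return ModelParams(sigma2_B=np.exp(rng.uniform(-3, 1)),
                       sigma2_F=np.exp(rng.uniform(-3, 1)),
                       alpha=np.exp(rng.uniform(-3, 1)),
                       theta_B=rng.uniform(-5, 5),
                       theta_F=rng.uniform(-5, 5), delta2=d2)


def all_model_specs(foreground="erato"):
    return [
        ModelSpec(Model.EQUAL_MEANS),
        ModelSpec(Model.UNEQUAL_MEANS),
        ModelSpec(Model.BM),
        ModelSpec(Model.BM_SHIFT, foreground),
        ModelSpec(Model.OU),
        ModelSpec(Model.OU_SHIFT, foreground),
    ]
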