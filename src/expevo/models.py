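"""The six models of species-mean expression evolution, with replicate noise.

Every model shares the same two-layer structure: a model for the vector of
latent species-mean expression levels, and independent Normal(mean_j,
delta2_j) replicate noise within species j.  The latent means are integrated
out analytically, so the likelihood of a gene's replicates is a closed-form
multivariate normal in the vector of species sample means plus independent
chi-square-type terms for the within-species scatter.

Models
------
EQUAL_MEANS    one global mean mu; no evolution.
UNEQUAL_MEANS  free per-species means mu_i; no phylogenetic structure.
BM             Brownian motion with drift rate sigma2; the unknown root state
               is removed by REML (the likelihood of contrasts).
BM_SHIFT       BM with a foreground branch evolving at its own rate sigma2_F
               against the background sigma2_B; REML as for BM.
OU             Ornstein-Uhlenbeck: drift sigma2, attraction alpha toward an
               optimum theta; the root is drawn from the stationary law
               Normal(theta, sigma2 / (2 alpha)), so tip variance is
               sigma2 / (2 alpha) independent of tree depth.
OU_SHIFT       OU whose foreground branch has its own rate sigma2_F and
               optimum theta_F; alpha is shared across regimes.

Units: branch lengths in million years (MY); expression in log2 FPKM;
sigma2 in log2^2 / MY; alpha in 1/MY.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

from .data import GeneObservations
from .trees import Phylogeny

__all__ = [
    "Model",
    "ModelSpec",
    "ModelParams",
    "PriorConfig",
    "ParamLayout",
    "GeneStats",
    "TreeCache",
    "bm_tip_covariance",
    "ou_tip_moments",
    "model_loglik",
    "simulate_gene",
    "loglik_batch",
]

LOG2PI = float(np.log(2.0 * np.pi))
ALPHA_FLOOR = 1e-12


class Model(str, Enum):
    EQUAL_MEANS = "EQUAL_MEANS"
    UNEQUAL_MEANS = "UNEQUAL_MEANS"
    BM = "BM"
    BM_SHIFT = "BM_SHIFT"
    OU = "OU"
    OU_SHIFT = "OU_SHIFT"

    @property
    def is_shift(self) -> bool:
        return self in (Model.BM_SHIFT, Model.OU_SHIFT)

    @property
    def is_phylogenetic(self) -> bool:
        return self not in (Model.EQUAL_MEANS, Model.UNEQUAL_MEANS)


@dataclass(frozen=True)
class ModelSpec:
    """A model identity plus, for shift models, the foreground branch key."""

    model: Model
    foreground: str | None = None

    def __post_init__(self) -> None:
        if self.model.is_shift and not self.foreground:
            raise ValueError(f"{self.model.value} requires a foreground branch")
        if not self.model.is_shift and self.foreground is not None:
            raise ValueError(f"{self.model.value} takes no foreground branch")

    def validate_against(self, tree: Phylogeny) -> None:
        if self.foreground is not None:
            tree.node_of(self.foreground)  # raises if absent

    def to_json(self) -> str:
        return json.dumps({"model": self.model.value,
                           "foreground": self.foreground})

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(model=Model(d["model"]), foreground=d.get("foreground"))


@dataclass
class ModelParams:
    """Parameter block for one model.

    Exactly the fields demanded by the :class:`ModelSpec` must be populated
    (checked by :meth:`validate`); ``delta2`` (per-species within-species
    variances) is required by every model.  ``root`` is the root state used
    when *simulating* BM-family genes; it does not enter the REML likelihood.
    """

    mu: float | None = None
    mu_i: dict[str, float] | None = None
    sigma2: float | None = None
    sigma2_B: float | None = None
    sigma2_F: float | None = None
    alpha: float | None = None
    theta: float | None = None
    theta_B: float | None = None
    theta_F: float | None = None
    delta2: dict[str, float] = field(default_factory=dict)
    root: float = 0.0

    _REQUIRED = {
        Model.EQUAL_MEANS: ("mu",),
        Model.UNEQUAL_MEANS: ("mu_i",),
        Model.BM: ("sigma2",),
        Model.BM_SHIFT: ("sigma2_B", "sigma2_F"),
        Model.OU: ("sigma2", "alpha", "theta"),
        Model.OU_SHIFT: ("sigma2_B", "sigma2_F", "alpha",
                         "theta_B", "theta_F"),
    }

    def validate(self, spec: ModelSpec, species: list[str]) -> None:
        need = self._REQUIRED[spec.model]
        for name in need:
            if getattr(self, name) is None:
                raise ValueError(f"{spec.model.value} requires {name}")
        all_fields = ("mu", "mu_i", "sigma2", "sigma2_B", "sigma2_F",
                      "alpha", "theta", "theta_B", "theta_F")
        for name in all_fields:
            if name not in need and getattr(self, name) is not None:
                raise ValueError(
                    f"{spec.model.value} does not use parameter {name}")
        for name in ("sigma2", "sigma2_B", "sigma2_F", "alpha"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if set(self.delta2) != set(species):
            raise ValueError("delta2 must name every species exactly once")
        # zero is tolerated for noise-free simulation; the likelihood needs
        # strictly positive values and will reject zeros itself
        if any(v < 0 for v in self.delta2.values()):
            raise ValueError("delta2 values must be non-negative")
        if self.mu_i is not None and set(self.mu_i) != set(species):
            raise ValueError("mu_i must name every species exactly once")

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if v is not None}
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls(**json.loads(text))


@dataclass
class PriorConfig:
    """Prior bounds: uniform for means/optima, log-uniform for positives.

    ``fixed`` pins named parameters at constants (they are then excluded from
    MCMC sampling and from the prior's dimensionality).
    """

    mean_bounds: tuple[float, float] = (-20.0, 20.0)
    rate_bounds: tuple[float, float] = (1e-5, 1e5)
    alpha_bounds: tuple[float, float] | None = None
    delta2_bounds: tuple[float, float] | None = None
    fixed: dict[str, float] = field(default_factory=dict)

    def bounds_for(self, name: str) -> tuple[float, float, bool]:
        """Return (lo, hi, log_scale) for a parameter name."""
        if name.startswith(("mu", "theta")):
            lo, hi = self.mean_bounds
            return lo, hi, False
        if name == "alpha":
            lo, hi = self.alpha_bounds or self.rate_bounds
        elif name.startswith("delta2"):
            lo, hi = self.delta2_bounds or self.rate_bounds
        else:
            lo, hi = self.rate_bounds
        if lo <= 0:
            raise ValueError(f"positive parameter {name} needs bounds > 0")
        return lo, hi, True


@dataclass
class ParamLayout:
    """Flat ordering of a model's parameters for vectorized evaluation."""

    spec: ModelSpec
    species: list[str]
    names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        m = self.spec.model
        if m is Model.EQUAL_MEANS:
            head = ["mu"]
        elif m is Model.UNEQUAL_MEANS:
            head = [f"mu_{sp}" for sp in self.species]
        elif m is Model.BM:
            head = ["sigma2"]
        elif m is Model.BM_SHIFT:
            head = ["sigma2_B", "sigma2_F"]
        elif m is Model.OU:
            head = ["sigma2", "alpha", "theta"]
        else:
            head = ["sigma2_B", "sigma2_F", "alpha", "theta_B", "theta_F"]
        self.names = head + [f"delta2_{sp}" for sp in self.species]
        self.n_head = len(head)

    @property
    def n_params(self) -> int:
        return len(self.names)

    def pack(self, params: ModelParams) -> np.ndarray:
        m = self.spec.model
        vals: list[float] = []
        if m is Model.EQUAL_MEANS:
            vals = [params.mu]
        elif m is Model.UNEQUAL_MEANS:
            vals = [params.mu_i[sp] for sp in self.species]
        elif m is Model.BM:
            vals = [params.sigma2]
        elif m is Model.BM_SHIFT:
            vals = [params.sigma2_B, params.sigma2_F]
        elif m is Model.OU:
            vals = [params.sigma2, params.alpha, params.theta]
        else:
            vals = [params.sigma2_B, params.sigma2_F, params.alpha,
                    params.theta_B, params.theta_F]
        vals += [params.delta2[sp] for sp in self.species]
        return np.asarray(vals, dtype=float)

    def unpack(self, x: np.ndarray) -> ModelParams:
        m = self.spec.model
        d2 = {sp: float(v) for sp, v in
              zip(self.species, x[self.n_head:])}
        h = x[: self.n_head]
        if m is Model.EQUAL_MEANS:
            return ModelParams(mu=float(h[0]), delta2=d2)
        if m is Model.UNEQUAL_MEANS:
            return ModelParams(mu_i={sp: float(v) for sp, v in
                                     zip(self.species, h)}, delta2=d2)
        if m is Model.BM:
            return ModelParams(sigma2=float(h[0]), delta2=d2)
        if m is Model.BM_SHIFT:
            return ModelParams(sigma2_B=float(h[0]), sigma2_F=float(h[1]),
                               delta2=d2)
        if m is Model.OU:
            return ModelParams(sigma2=float(h[0]), alpha=float(h[1]),
                               theta=float(h[2]), delta2=d2)
        return ModelParams(sigma2_B=float(h[0]), sigma2_F=float(h[1]),
                           alpha=float(h[2]), theta_B=float(h[3]),
                           theta_F=float(h[4]), delta2=d2)


# ---------------------------------------------------------------------------
# Tree-derived caches
# ---------------------------------------------------------------------------


class TreeCache:
    """Precomputed tip-pair geometry for one phylogeny.

    Holds the shared-path-length matrix (BM covariance at unit rate), tip
    pairwise distances, MRCA node indices and node depths, so per-likelihood
    work reduces to a few dense 5x5 (S x S) operations.
    """

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        self.tips = tree.tips
        self.S = len(self.tips)
        self.depth_mrca = tree.mrca_depth_matrix()
        depths = np.diag(self.depth_mrca).copy()
        self.tip_depths = depths
        self.dist = depths[:, None] + depths[None, :] - 2.0 * self.depth_mrca
        # MRCA node indices for the OU recursion's covariance lookup
        self.mrca_node = np.zeros((self.S, self.S), dtype=np.int64)
        anc = []
        for lab in self.tips:
            chain = []
            i = tree.tip_index[lab]
            while i != -1:
                chain.append(i)
                i = tree.parent[i]
            anc.append(chain)
        for a in range(self.S):
            for b in range(self.S):
                common = set(anc[a]) & set(anc[b])
                self.mrca_node[a, b] = max(common,
                                           key=lambda i: tree.depth(i))
        # shared path length = depth of MRCA (ultrametric or not: the length
        # of the root-to-MRCA path)
        self.V0 = self.depth_mrca.copy()
        np.fill_diagonal(self.V0, depths)

    def tip_pos(self, label: str) -> int:
        return self.tips.index(label)

    def tip_edge_length(self, label: str) -> float:
        return float(self.tree.blen[self.tree.tip_index[label]])


@dataclass
class GeneStats:
    """Sufficient statistics of one or many genes on a fixed layout.

    ``xbar``/``ss`` are (K, S): per-gene species sample means and
    within-species sums of squares around the mean; ``n`` is the (S,)
    replicate count vector shared by all K genes.
    """

    xbar: np.ndarray
    ss: np.ndarray
    n: np.ndarray
    species: list[str]

    @classmethod
    def from_gene(cls, gene: GeneObservations, species: list[str]
                  ) -> "GeneStats":
        if set(gene.species) != set(species):
            raise ValueError(
                f"gene {gene.gene}: species {gene.species} do not match "
                f"tree tips {species}")
        xbar = np.array([[gene.values[sp].mean() for sp in species]])
        ss = np.array([[((gene.values[sp] - gene.values[sp].mean()) ** 2).sum()
                        for sp in species]])
        n = np.array([len(gene.values[sp]) for sp in species], dtype=float)
        return cls(xbar=xbar, ss=ss, n=n, species=species)

    @classmethod
    def from_matrix(cls, x: np.ndarray, counts: np.ndarray,
                    species: list[str]) -> "GeneStats":
        """Build from raw replicate draws x of shape (K, total_samples),
        whose columns are grouped by species in ``species`` order with
        ``counts`` replicates each."""
        idx = np.concatenate([[0], np.cumsum(counts)]).astype(int)
        xbar = np.stack([x[:, idx[j]:idx[j + 1]].mean(axis=1)
                         for j in range(len(species))], axis=1)
        ss = np.stack([((x[:, idx[j]:idx[j + 1]]
                         - xbar[:, j][:, None]) ** 2).sum(axis=1)
                       for j in range(len(species))], axis=1)
        return cls(xbar=xbar, ss=ss, n=np.asarray(counts, dtype=float),
                   species=species)

    @classmethod
    def stack(cls, items: list["GeneStats"]) -> "GeneStats":
        first = items[0]
        if any(s.species != first.species or
               not np.array_equal(s.n, first.n) for s in items):
            raise ValueError("stacked statistics need identical layouts")
        return cls(xbar=np.vstack([s.xbar for s in items]),
                   ss=np.vstack([s.ss for s in items]),
                   n=first.n, species=first.species)

    @property
    def K(self) -> int:
        return self.xbar.shape[0]


# ---------------------------------------------------------------------------
# Covariance builders
# ---------------------------------------------------------------------------


def bm_tip_covariance(tree: Phylogeny,
                      branch_rates: float | Mapping[str, float] = 1.0
                      ) -> np.ndarray:
    """Tip covariance under BM with per-edge rates.

    Entry (i, j) is the sum over edges on the shared root-to-MRCA(i, j) path
    of rate_k * length_k.  ``branch_rates`` is either a single rate or a
    mapping from edge key to rate (missing keys are an error).
    """
    if not isinstance(branch_rates, Mapping):
        cache = TreeCache(tree)
        return float(branch_rates) * cache.V0
    acc = np.zeros(tree.n_nodes)
    for i in range(1, tree.n_nodes):
        key = tree.node_keys[i]
        if key not in branch_rates:
            raise ValueError(f"no rate given for edge {key!r}")
        r = float(branch_rates[key])
        if r <= 0:
            raise ValueError(f"rate for edge {key!r} must be > 0")
        acc[i] = acc[tree.parent[i]] + r * tree.blen[i]
    cache = TreeCache(tree)
    out = np.empty((cache.S, cache.S))
    for a in range(cache.S):
        for b in range(cache.S):
            out[a, b] = acc[cache.mrca_node[a, b]]
    return out


def ou_tip_moments(tree: Phylogeny, sigma2: float, alpha: float,
                   theta: float | Mapping[str, float],
                   *, sigma2_map: Mapping[str, float] | None = None,
                   root_theta: float | None = None,
                   root_sigma2: float | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance matrix of tip values under OU.

    The root state is drawn from the stationary distribution
    Normal(root_theta, root_sigma2 / (2 alpha)); with a constant optimum this
    gives Var(tip) = sigma2 / (2 alpha) and Cov(i, j) = (sigma2 / (2 alpha))
    * exp(-alpha * d_ij) for tree distance d_ij.  ``theta`` may be a mapping
    from edge key to optimum (unnamed edges fall back to ``root_theta``),
    which is how the foreground optimum of OU_SHIFT enters.
    """
    if alpha < ALPHA_FLOOR:
        raise ValueError(
            f"alpha={alpha} below {ALPHA_FLOOR}; use the BM limit instead")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if isinstance(theta, Mapping):
        if root_theta is None:
            raise ValueError("per-edge theta requires an explicit root_theta")
        theta_of = lambda key: float(theta.get(key, root_theta))  # noqa: E731
        th_root = root_theta
    else:
        theta_of = lambda key: float(theta)  # noqa: E731
        th_root = float(theta) if root_theta is None else root_theta
    s2_of = (lambda key: float(sigma2_map.get(key, sigma2))) \
        if sigma2_map else (lambda key: sigma2)
    s2_root = sigma2 if root_sigma2 is None else root_sigma2

    n = tree.n_nodes
    mean = np.empty(n)
    var = np.empty(n)
    mean[0] = th_root
    var[0] = s2_root / (2.0 * alpha)
    for i in range(1, n):
        p = tree.parent[i]
        t = tree.blen[i]
        key = tree.node_keys[i]
        phi = np.exp(-alpha * t)
        mean[i] = phi * mean[p] + (1.0 - phi) * theta_of(key)
        var[i] = phi * phi * var[p] \
            - s2_of(key) * np.expm1(-2.0 * alpha * t) / (2.0 * alpha)
    cache = TreeCache(tree)
    tip_idx = [tree.tip_index[lab] for lab in cache.tips]
    mvec = mean[tip_idx]
    cov = np.empty((cache.S, cache.S))
    for a in range(cache.S):
        for b in range(cache.S):
            m = cache.mrca_node[a, b]
            lag = (cache.tip_depths[a] - tree.depth(m)) \
                + (cache.tip_depths[b] - tree.depth(m))
            cov[a, b] = np.exp(-alpha * lag) * var[m]
    return mvec, cov


# ---------------------------------------------------------------------------
# Batched likelihood kernels
# ---------------------------------------------------------------------------


def _tri_solve_lower(L: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve L y = B for batched lower-triangular L (K,S,S), B (K,S,m)."""
    S = L.shape[1]
    Y = np.empty_like(B)
    for i in range(S):
        acc = B[:, i, :].copy()
        if i:
            acc -= np.einsum("kj,kjm->km", L[:, i, :i], Y[:, :i, :])
        Y[:, i, :] = acc / L[:, i, i][:, None]
    return Y


def _chol(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched Cholesky returning (L, ok mask); failures yield identity."""
    try:
        return np.linalg.cholesky(W), np.ones(W.shape[0], dtype=bool)
    except np.linalg.LinAlgError:
        K = W.shape[0]
        ok = np.ones(K, dtype=bool)
        L = np.empty_like(W)
        eye = np.eye(W.shape[1])
        for k in range(K):
            try:
                L[k] = np.linalg.cholesky(W[k])
            except np.linalg.LinAlgError:
                ok[k] = False
                L[k] = eye
        return L, ok


def _within_term(d2: np.ndarray, stats: GeneStats) -> np.ndarray:
    """Log density contribution of within-species scatter, shape (K,).

    Sum_j [ -((n_j - 1)/2) log(2 pi d2_j) - SS_j / (2 d2_j) ].
    """
    n = stats.n[None, :]
    return (-(0.5 * (n - 1.0)) * (LOG2PI + np.log(d2))
            - stats.ss / (2.0 * d2)).sum(axis=1)


def _mvn_full(xbar: np.ndarray, mean: np.ndarray, W: np.ndarray
              ) -> np.ndarray:
    """Batched log MVN density of xbar (K,S) under N(mean, W)."""
    S = xbar.shape[1]
    L, ok = _chol(W)
    r = (xbar - mean)[:, :, None]
    y = _tri_solve_lower(L, r)[:, :, 0]
    q = (y * y).sum(axis=1)
    logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
    out = -0.5 * (S * LOG2PI + logdet + q)
    out[~ok] = -np.inf
    return out


def _mvn_reml(xbar: np.ndarray, W: np.ndarray, stats: GeneStats
              ) -> np.ndarray:
    """Batched REML (contrast) log density of the species-mean layer.

    This is the log density of any orthonormal set of individual-level
    contrasts, restricted to its between-species part; combined with
    :func:`_within_term` it equals the individual-level contrast likelihood.
    """
    K, S = W.shape[0], W.shape[1]
    L, ok = _chol(W)
    rhs = np.empty((K, S, 2))
    rhs[:, :, 0] = xbar
    rhs[:, :, 1] = 1.0
    Y = _tri_solve_lower(L, rhs)
    qxx = (Y[:, :, 0] * Y[:, :, 0]).sum(axis=1)
    qx1 = (Y[:, :, 0] * Y[:, :, 1]).sum(axis=1)
    q11 = (Y[:, :, 1] * Y[:, :, 1]).sum(axis=1)
    resid = qxx - qx1 * qx1 / q11
    logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
    n = stats.n
    const = np.log(n).sum() - np.log(n.sum())
    out = -0.5 * ((S - 1) * LOG2PI + logdet + const + np.log(q11) + resid)
    out[~ok] = -np.inf
    return out


def _ou_cov_batch(cache: TreeCache, sigma2: np.ndarray, alpha: np.ndarray,
                  fg: int | None = None, sigma2_F: np.ndarray | None = None,
                  ) -> np.ndarray:
    """(K,S,S) OU tip covariance; optional foreground tip rate shift."""
    a = alpha[:, None, None]
    base = (sigma2[:, None, None] / (2.0 * a)) * np.exp(-a * cache.dist)
    if fg is not None:
        e = cache.tip_edge_length(cache.tips[fg])
        decay = np.exp(-2.0 * alpha * e)
        var_f = decay * sigma2 / (2.0 * alpha) \
            - sigma2_F * np.expm1(-2.0 * alpha * e) / (2.0 * alpha)
        base[:, fg, fg] = var_f
    return base


def loglik_batch(spec: ModelSpec, cache: TreeCache, stats: GeneStats,
                 x: np.ndarray) -> np.ndarray:
    """Vectorized log likelihood for K (gene, parameter) pairs.

    ``x`` has shape (K, P) on the natural parameter scale, in
    :class:`ParamLayout` order.  BM-family models return the REML (contrast)
    likelihood; the others the full likelihood.  Parameter vectors yielding a
    numerically non-positive-definite covariance get -inf.
    """
    m = spec.model
    S = cache.S
    layout = ParamLayout(spec, cache.tips)
    d2 = x[:, layout.n_head:]
    D = d2 / stats.n[None, :]
    within = _within_term(d2, stats)
    half_log_n = 0.5 * np.log(stats.n).sum()

    if m is Model.EQUAL_MEANS:
        mean = np.repeat(x[:, 0:1], S, axis=1)
        ll = (-0.5 * (LOG2PI + np.log(D))
              - (stats.xbar - mean) ** 2 / (2.0 * D)).sum(axis=1)
        return within - half_log_n + ll
    if m is Model.UNEQUAL_MEANS:
        mean = x[:, :S]
        ll = (-0.5 * (LOG2PI + np.log(D))
              - (stats.xbar - mean) ** 2 / (2.0 * D)).sum(axis=1)
        return within - half_log_n + ll

    Dmat = np.zeros((x.shape[0], S, S))
    idx = np.arange(S)
    Dmat[:, idx, idx] = D

    if m is Model.BM:
        W = x[:, 0][:, None, None] * cache.V0[None] + Dmat
        return within + _mvn_reml(stats.xbar, W, stats)
    if m is Model.BM_SHIFT:
        fg = cache.tip_pos(spec.foreground)
        e = cache.tip_edge_length(spec.foreground)
        W = x[:, 0][:, None, None] * cache.V0[None] + Dmat
        W[:, fg, fg] += (x[:, 1] - x[:, 0]) * e
        return within + _mvn_reml(stats.xbar, W, stats)
    if m is Model.OU:
        sigma2, alpha, theta = x[:, 0], x[:, 1], x[:, 2]
        W = _ou_cov_batch(cache, sigma2, alpha) + Dmat
        mean = np.repeat(theta[:, None], S, axis=1)
        return within - half_log_n + _mvn_full(stats.xbar, mean, W)
    # OU_SHIFT
    s2B, s2F, alpha = x[:, 0], x[:, 1], x[:, 2]
    thB, thF = x[:, 3], x[:, 4]
    fg = cache.tip_pos(spec.foreground)
    e = cache.tip_edge_length(spec.foreground)
    W = _ou_cov_batch(cache, s2B, alpha, fg=fg, sigma2_F=s2F) + Dmat
    mean = np.repeat(thB[:, None], S, axis=1)
    phi = np.exp(-alpha * e)
    mean[:, fg] = phi * thB + (1.0 - phi) * thF
    return within - half_log_n + _mvn_full(stats.xbar, mean, W)


def model_loglik(spec: ModelSpec, params: ModelParams,
                 gene: GeneObservations, tree: Phylogeny) -> float:
    """Log likelihood of one gene's replicates under one model.

    Latent species means are integrated out analytically.  For BM-family
    models this is the REML likelihood (translation-invariant: the unknown
    root state drops out); EQUAL/UNEQUAL/OU-family return the full
    likelihood (the OU root state follows the stationary distribution and is
    not a free parameter).
    """
    spec.validate_against(tree)
    params.validate(spec, tree.tips)
    cache = TreeCache(tree)
    stats = GeneStats.from_gene(gene, cache.tips)
    layout = ParamLayout(spec, cache.tips)
    x = layout.pack(params)[None, :]
    out = float(loglik_batch(spec, cache, stats, x)[0])
    if not np.isfinite(out) and np.isneginf(out):
        raise ValueError(
            f"covariance not positive definite for {spec.model.value} "
            f"with params {params.to_json()}")
    return out


# ---------------------------------------------------------------------------
# Exact simulation
# ---------------------------------------------------------------------------


def _species_means_one(spec: ModelSpec, params: ModelParams,
                       tree: Phylogeny, rng: np.random.Generator
                       ) -> dict[str, float]:
    m = spec.model
    tips = tree.tips
    if m is Model.EQUAL_MEANS:
        return {sp: float(params.mu) for sp in tips}
    if m is Model.UNEQUAL_MEANS:
        return {sp: float(params.mu_i[sp]) for sp in tips}

    state = np.empty(tree.n_nodes)
    if m in (Model.BM, Model.BM_SHIFT):
        state[0] = params.root
        for i in range(1, tree.n_nodes):
            key = tree.node_keys[i]
            if m is Model.BM_SHIFT:
                s2 = params.sigma2_F if key == spec.foreground \
                    else params.sigma2_B
            else:
                s2 = params.sigma2
            state[i] = state[tree.parent[i]] \
                + rng.normal(0.0, np.sqrt(s2 * tree.blen[i]))
    else:
        alpha = params.alpha
        if m is Model.OU:
            s2_bg, th_bg = params.sigma2, params.theta
            th_of = lambda key: params.theta  # noqa: E731
            s2_of = lambda key: params.sigma2  # noqa: E731
        else:
            s2_bg, th_bg = params.sigma2_B, params.theta_B
            th_of = lambda key: (params.theta_F  # noqa: E731
                                 if key == spec.foreground
                                 else params.theta_B)
            s2_of = lambda key: (params.sigma2_F  # noqa: E731
                                 if key == spec.foreground
                                 else params.sigma2_B)
        state[0] = rng.normal(th_bg, np.sqrt(s2_bg / (2.0 * alpha)))
        for i in range(1, tree.n_nodes):
            key = tree.node_keys[i]
            phi = np.exp(-alpha * tree.blen[i])
            v = -s2_of(key) * np.expm1(-2.0 * alpha * tree.blen[i]) \
                / (2.0 * alpha)
            state[i] = th_of(key) + phi * (state[tree.parent[i]] - th_of(key)) \
                + rng.normal(0.0, np.sqrt(v))
    return {sp: float(state[tree.tip_index[sp]]) for sp in tips}


def simulate_gene(spec: ModelSpec, params: ModelParams, tree: Phylogeny,
                  replicates: Mapping[str, int],
                  seed: int | np.random.Generator) -> GeneObservations:
    """Simulate one gene by exact recursion down the tree.

    Each child node's latent mean is drawn from its exact conditional normal
    given the parent (no time discretization); replicates are then drawn as
    Normal(species mean, delta2_j).  Reproducible under a fixed seed.
    """
    spec.validate_against(tree)
    params.validate(spec, tree.tips)
    for sp in tree.tips:
        if replicates.get(sp, 0) < 1:
            raise ValueError(f"replicate count for {sp} must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    means = _species_means_one(spec, params, tree, rng)
    values = {sp: rng.normal(means[sp], np.sqrt(params.delta2[sp]),
                             size=replicates[sp])
              for sp in tree.tips}
    return GeneObservations(gene="sim", values=values)
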