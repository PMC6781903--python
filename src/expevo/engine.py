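"""Metropolis-Hastings MCMC, stepping-stone marginal likelihoods, Bayes factors.

The sampler is a random-walk Metropolis scheme with one scalar proposal per
parameter: sliding-window proposals (reflecting at the prior bounds) for
interval-bounded parameters, and the same sliding window on the log scale for
positive parameters (equivalent to a multiplicative scaling move).  Because
priors are uniform on the sampling scale (uniform for means/optima,
log-uniform for rates/variances/alpha), the tempered target at power beta is
simply ``beta * loglik`` plus a constant, and a chain at beta = 0 samples the
prior exactly.

Proposal widths are auto-tuned toward a target acceptance rate during burn-in
only, so the main chain is a valid Markov chain.  All chain arithmetic is
vectorized over a batch axis: the public single-gene functions run a batch of
size one, and the batched entry points (used by the calibration studies) run
hundreds of independent chains in lockstep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data import GeneObservations
from .models import (
    GeneStats,
    Model,
    ModelParams,
    ModelSpec,
    ParamLayout,
    PriorConfig,
    TreeCache,
    loglik_batch,
)
from .trees import Phylogeny

__all__ = [
    "McmcSettings",
    "PosteriorTrace",
    "MarginalLikelihood",
    "ModelComparison",
    "run_mcmc",
    "stepping_stone",
    "fit_batch",
    "stepping_stone_batch",
    "bayes_factor",
    "model_probabilities",
    "prob_to_bf",
    "beta_schedule",
]

TARGET_ACCEPTANCE = 0.44


@dataclass
class McmcSettings:
    """Chain schedule; the defaults give 5000 retained samples.

    ``iterations`` must be divisible by ``thinning``.  Every free parameter
    is updated ``updates_per_param`` times per iteration, in an order
    re-randomized each iteration.
    """

    burnin: int = 2000
    tuning_interval: int = 100
    iterations: int = 50_000
    thinning: int = 10
    updates_per_param: int = 2
    seed: int = 0
    init_at_sample_mean: bool = False

    def __post_init__(self) -> None:
        if self.iterations % self.thinning:
            raise ValueError("iterations must be a multiple of thinning")
        if self.burnin < 0 or self.iterations <= 0 or self.thinning <= 0:
            raise ValueError("invalid MCMC schedule")

    @property
    def n_retained(self) -> int:
        return self.iterations // self.thinning


@dataclass
class PosteriorTrace:
    """Retained samples from one MCMC run, on the natural parameter scale."""

    names: list[str]
    iteration: np.ndarray        # (R,)
    samples: np.ndarray          # (R, P)
    loglik: np.ndarray           # (R,)
    acceptance: dict[str, float]
    scales: dict[str, float]

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]

    def posterior_mean(self, name: str) -> float:
        return float(self.column(name).mean())

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.samples, columns=self.names)
        df.insert(0, "iteration", self.iteration)
        df["loglik"] = self.loglik
        df.to_csv(path, sep="\t", index=False)


@dataclass
class MarginalLikelihood:
    """A stepping-stone estimate of one model's log marginal likelihood."""

    spec: ModelSpec
    log_marginal: float
    stones: int
    betas: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        if len(b) != self.stones or not np.all(np.diff(b) > 0) \
                or b[-1] != 1.0 or b[0] <= 0:
            raise ValueError("betas must be strictly increasing in (0, 1] "
                             "with last value 1 and one value per stone")
        self.betas = b


def beta_schedule(stones: int, shape: float = 0.3) -> np.ndarray:
    """Stepping-stone powers: quantiles of Beta(shape, 1) at equally spaced
    probabilities 1/stones, ..., 1.  The small shape concentrates stones near
    beta = 0 where the power-posterior integrand changes fastest."""
    if stones < 2:
        raise ValueError("need at least 2 stones")
    p = np.arange(1, stones + 1) / stones
    return p ** (1.0 / shape)


# ---------------------------------------------------------------------------
# Batched Metropolis-Hastings core
# ---------------------------------------------------------------------------


class _Chains:
    """K independent MH chains on the same model/tree/replicate layout."""

    MAX_INIT_RETRIES = 100

    def __init__(self, spec: ModelSpec, cache: TreeCache, stats: GeneStats,
                 priors: PriorConfig, settings: McmcSettings,
                 rng: np.random.Generator, beta: float = 1.0):
        self.spec = spec
        self.cache = cache
        self.stats = stats
        self.settings = settings
        self.rng = rng
        self.beta = beta
        self.layout = ParamLayout(spec, cache.tips)
        self.K = stats.K

        names = self.layout.names
        self.names = names
        self.P = len(names)
        self.log_flags = np.zeros(self.P, dtype=bool)
        self.lo = np.empty(self.P)
        self.hi = np.empty(self.P)
        fixed_mask = np.zeros(self.P, dtype=bool)
        fixed_vals = np.zeros(self.P)
        for j, name in enumerate(names):
            lo, hi, is_log = priors.bounds_for(name)
            self.log_flags[j] = is_log
            self.lo[j], self.hi[j] = (np.log(lo), np.log(hi)) if is_log \
                else (lo, hi)
            if name in priors.fixed:
                fixed_mask[j] = True
                fixed_vals[j] = priors.fixed[name]
        self.fixed_mask = fixed_mask
        self.free = np.flatnonzero(~fixed_mask)
        self.width = self.hi - self.lo

        # state in sampling space; fixed entries hold transformed constants
        self.z = np.empty((self.K, self.P))
        for j in range(self.P):
            if fixed_mask[j]:
                v = fixed_vals[j]
                self.z[:, j] = np.log(v) if self.log_flags[j] else v
        self.scales = np.full((self.K, self.P), 0.0)
        for j in self.free:
            self.scales[:, j] = 0.1 * self.width[j]
        self.acc = np.zeros((self.K, self.P))
        self.try_ = np.zeros((self.K, self.P))
        self.ll = np.full(self.K, -np.inf)

    # -- helpers -----------------------------------------------------------

    def _natural(self, z: np.ndarray) -> np.ndarray:
        x = z.copy()
        x[:, self.log_flags] = np.exp(x[:, self.log_flags])
        return x

    def _loglik(self, z: np.ndarray) -> np.ndarray:
        return loglik_batch(self.spec, self.cache, self.stats,
                            self._natural(z))

    def initialize(self) -> None:
        for attempt in range(self.MAX_INIT_RETRIES):
            bad = ~np.isfinite(self.ll)
            if not bad.any():
                return
            nb = int(bad.sum())
            draw = self.lo + self.width * self.rng.uniform(
                size=(nb, self.P))
            z = self.z[bad]
            z[:, self.free] = draw[:, self.free]
            if self.settings.init_at_sample_mean:
                grand = (self.stats.xbar * self.stats.n).sum(axis=1) \
                    / self.stats.n.sum()
                for j, name in enumerate(self.names):
                    if not self.fixed_mask[j] and \
                            name.startswith(("mu", "theta")):
                        z[:, j] = np.clip(grand[bad], self.lo[j], self.hi[j])
            self.z[bad] = z
            self.ll[bad] = self._loglik(self.z)[bad]
        raise RuntimeError(
            "could not find a finite-likelihood initialization after "
            f"{self.MAX_INIT_RETRIES} attempts")

    def _reflect(self, v: np.ndarray, j: int) -> np.ndarray:
        lo, hi = self.lo[j], self.hi[j]
        period = 2.0 * (hi - lo)
        y = np.mod(v - lo, period)
        return lo + np.minimum(y, period - y)

    def _update_one(self, j: int) -> None:
        step = self.scales[:, j] * (2.0 * self.rng.uniform(size=self.K) - 1.0)
        zp = self.z.copy()
        zp[:, j] = self._reflect(zp[:, j] + step, j)
        llp = self._loglik(zp)
        with np.errstate(invalid="ignore"):
            delta = self.beta * (llp - self.ll)
        delta = np.where(np.isneginf(llp), -np.inf, delta)
        accept = np.log(self.rng.uniform(size=self.K)) < delta
        self.z[accept, j] = zp[accept, j]
        self.ll[accept] = llp[accept]
        self.acc[:, j] += accept
        self.try_[:, j] += 1.0

    def _iterate(self, n_iter: int, tune: bool,
                 collect_every: int | None = None,
                 collect_loglik: bool = False):
        """Run n_iter iterations; optionally tune, collect samples, or
        record thinned log likelihoods (for the stepping-stone ratios)."""
        upp = self.settings.updates_per_param
        collected_z = []
        collected_ll = []
        ss_terms = [] if collect_loglik else None
        for it in range(1, n_iter + 1):
            order = np.repeat(self.free, upp)
            self.rng.shuffle(order)
            for j in order:
                self._update_one(int(j))
            if tune and it % self.settings.tuning_interval == 0:
                rates = np.divide(self.acc, np.maximum(self.try_, 1.0))
                factor = np.exp(rates - TARGET_ACCEPTANCE)
                self.scales[:, self.free] *= factor[:, self.free]
                for j in self.free:
                    np.clip(self.scales[:, j], 1e-6 * self.width[j],
                            self.width[j], out=self.scales[:, j])
                self.acc[:] = 0.0
                self.try_[:] = 0.0
            if collect_every and it % collect_every == 0:
                collected_z.append(self.z.copy())
                collected_ll.append(self.ll.copy())
            if ss_terms is not None and it % self.settings.thinning == 0:
                ss_terms.append(self.ll.copy())
        return collected_z, collected_ll, ss_terms

    def acceptance_rates(self) -> np.ndarray:
        return np.divide(self.acc, np.maximum(self.try_, 1.0))


def _prepare(spec: ModelSpec, tree: Phylogeny,
             stats: GeneStats) -> tuple[TreeCache, GeneStats]:
    spec.validate_against(tree)
    cache = TreeCache(tree)
    if stats.species != cache.tips:
        raise ValueError("statistics species order does not match tree tips")
    return cache, stats


def run_mcmc(spec: ModelSpec, gene: GeneObservations, tree: Phylogeny,
             priors: PriorConfig | None = None,
             settings: McmcSettings | None = None) -> PosteriorTrace:
    """Sample the posterior of one model for one gene.

    Returns a trace of ``iterations / thinning`` retained samples with
    per-parameter acceptance rates and final tuned proposal scales.
    Bit-reproducible for a fixed ``settings.seed``.
    """
    priors = priors or PriorConfig()
    settings = settings or McmcSettings()
    cache, stats = _prepare(spec, tree,
                            GeneStats.from_gene(gene, tree.tips))
    rng = np.random.default_rng(settings.seed)
    ch = _Chains(spec, cache, stats, priors, settings, rng)
    ch.initialize()
    ch._iterate(settings.burnin, tune=True)
    ch.acc[:] = 0.0
    ch.try_[:] = 0.0
    zs, lls, _ = ch._iterate(settings.iterations, tune=False,
                             collect_every=settings.thinning)
    z = np.stack([s[0] for s in zs], axis=0)
    x = z.copy()
    x[:, ch.log_flags] = np.exp(x[:, ch.log_flags])
    rates = ch.acceptance_rates()[0]
    return PosteriorTrace(
        names=list(ch.names),
        iteration=np.arange(1, len(zs) + 1) * settings.thinning,
        samples=x,
        loglik=np.array([v[0] for v in lls]),
        acceptance={ch.names[j]: float(rates[j]) for j in ch.free},
        scales={ch.names[j]: float(ch.scales[0, j]) for j in ch.free},
    )


def fit_batch(spec: ModelSpec, tree: Phylogeny, stats: GeneStats,
              priors: PriorConfig | None = None,
              settings: McmcSettings | None = None,
              rng: np.random.Generator | None = None
              ) -> tuple[list[str], np.ndarray]:
    """Posterior samples for K genes at once (same tree and layout).

    Returns (parameter names, samples of shape (R, K, P)) on the natural
    scale.  Used by the calibration studies, where hundreds of single-gene
    fits share one vectorized chain sweep.
    """
    priors = priors or PriorConfig()
    settings = settings or McmcSettings()
    cache, stats = _prepare(spec, tree, stats)
    rng = rng or np.random.default_rng(settings.seed)
    ch = _Chains(spec, cache, stats, priors, settings, rng)
    ch.initialize()
    ch._iterate(settings.burnin, tune=True)
    zs, _, _ = ch._iterate(settings.iterations, tune=False,
                           collect_every=settings.thinning)
    z = np.stack(zs, axis=0)
    x = z.copy()
    x[:, :, ch.log_flags] = np.exp(x[:, :, ch.log_flags])
    return list(ch.names), x


def stepping_stone_batch(spec: ModelSpec, tree: Phylogeny, stats: GeneStats,
                         priors: PriorConfig | None = None,
                         settings: McmcSettings | None = None,
                         stones: int = 128,
                         rng: np.random.Generator | None = None
                         ) -> np.ndarray:
    """Stepping-stone log marginal likelihoods for K genes at once.

    One power-posterior chain per stone; stone k samples at power
    beta_{k-1} (beta_0 = 0, i.e. the prior) and contributes
    ``log mean L^(beta_k - beta_{k-1})``; the chain then warm-starts the next
    stone.  Each stone reruns the burn-in/tuning schedule.
    """
    priors = priors or PriorConfig()
    settings = settings or McmcSettings()
    cache, stats = _prepare(spec, tree, stats)
    rng = rng or np.random.default_rng(settings.seed)
    betas = beta_schedule(stones)
    ch = _Chains(spec, cache, stats, priors, settings, rng, beta=0.0)
    ch.initialize()
    logml = np.zeros(stats.K)
    b_prev = 0.0
    for k in range(stones):
        ch.beta = b_prev
        ch._iterate(settings.burnin, tune=True)
        _, _, terms = ch._iterate(settings.iterations, tune=False,
                                  collect_loglik=True)
        ll = np.stack(terms, axis=0)  # (n, K)
        contrib = logsumexp((betas[k] - b_prev) * ll, axis=0) \
            - np.log(ll.shape[0])
        if not np.all(np.isfinite(contrib)):
            bad = np.flatnonzero(~np.isfinite(contrib))
            raise RuntimeError(
                f"non-finite stepping-stone estimate at stone {k + 1} "
                f"(beta={betas[k]:.4g}) for batch items {bad.tolist()}")
        logml += contrib
        b_prev = betas[k]
    return logml


def stepping_stone(spec: ModelSpec, gene: GeneObservations, tree: Phylogeny,
                   priors: PriorConfig | None = None,
                   settings: McmcSettings | None = None,
                   stones: int = 128) -> MarginalLikelihood:
    """Stepping-stone estimate of one model's log marginal likelihood."""
    stats = GeneStats.from_gene(gene, tree.tips)
    logml = stepping_stone_batch(spec, tree, stats, priors, settings, stones)
    return MarginalLikelihood(spec=spec, log_marginal=float(logml[0]),
                              stones=stones, betas=beta_schedule(stones))


# ---------------------------------------------------------------------------
# Bayes factors and model probabilities
# ---------------------------------------------------------------------------


def _logml(m) -> float:
    return m.log_marginal if isinstance(m, MarginalLikelihood) else float(m)


def bayes_factor(ml_a, ml_b) -> float:
    """BF(A, B) = exp(log ML_A - log ML_B)."""
    return float(np.exp(_logml(ml_a) - _logml(ml_b)))


def model_probabilities(mls) -> np.ndarray:
    """Posterior model probabilities under equal prior model weights."""
    logs = np.array([_logml(m) for m in mls])
    w = logs - logsumexp(logs)
    return np.exp(w)


def prob_to_bf(p: float) -> float:
    """Two-model Bayes factor equivalent to a model probability p."""
    if not 0.0 < p < 1.0:
        raise ValueError("model probability must be strictly in (0, 1)")
    return p / (1.0 - p)


@dataclass
class ModelComparison:
    """Per-gene marginal likelihoods, Bayes factors and model probabilities."""

    marginals: list[MarginalLikelihood]
    probabilities: np.ndarray = field(init=False)

    POSITIVE = 0.75   # model probability threshold, BF > 3
    STRONG = 0.95     # model probability threshold, BF > 20

    def __post_init__(self) -> None:
        self.probabilities = model_probabilities(self.marginals)

    def bayes_factor(self, i: int, j: int) -> float:
        return bayes_factor(self.marginals[i], self.marginals[j])

    def support_call(self, i: int) -> str:
        p = self.probabilities[i]
        if p > self.STRONG:
            return "strong"
        if p > self.POSITIVE:
            return "positive"
        return "none"

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for i, m in enumerate(self.marginals):
            rows.append({
                "model": m.spec.model.value,
                "foreground": m.spec.foreground or "",
                "log_marginal": m.log_marginal,
                "probability": self.probabilities[i],
                "support": self.support_call(i),
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
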