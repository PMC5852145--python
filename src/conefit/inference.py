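"""Bayesian machinery: likelihood, posterior sampling, evidence, optimization.

Parameters split into a cell-common core vector theta (Hill constants,
coefficients, interaction gains of the active pathways) and one peripheral
block per series (V_K, tau_S, A_Cl, A_Na).  All samplers and optimizers work
on a flat vector ordered [core | phi_1 | phi_2 | ...]; ParameterSpace owns the
packing.

The marginal likelihood (evidence) is estimated by stepping-stone sampling
over a power-posterior ladder; the estimator is generic over a VectorProblem
so its correctness is pinned by conjugate-Gaussian oracles in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .dataset import Dataset
from .model import (
    ConditionParams,
    CoreParams,
    ModelTopology,
    PeripheralParams,
    Trajectory,
    simulate_grid,
)
from .preprocess import MpTimeSeries
from .priors import PriorSet, TruncatedNormalPrior

__all__ = [
    "ParameterSpace",
    "LikelihoodEngine",
    "VectorProblem",
    "Chain",
    "FitResult",
    "EvidenceResult",
    "McmcConfig",
    "EvidenceConfig",
    "OptConfig",
    "log_prior_density",
    "log_likelihood_series",
    "total_log_likelihood",
    "sample_posterior",
    "posterior_mean_estimate",
    "estimate_log_evidence",
    "stepping_stone",
    "maximize_log_likelihood",
    "fit_peripherals",
    "information_criteria",
]

_LOG_SQRT2PI = 0.5 * math.log(2.0 * math.pi)

CORE_CANDIDATES = ("K_X", "n_X", "K_Y", "n_Y")


# ---------------------------------------------------------------------------
# parameter vector layout


class ParameterSpace:
    """Flat-vector view of (theta, phi_1..phi_I) for one topology.

    Core entries are the candidate core parameters that have priors plus the
    interaction gains of the topology's active pathways; gains of absent
    pathways are pinned to zero, which is what makes nested models nested.
    """

    def __init__(
        self,
        topology: ModelTopology,
        priors: PriorSet,
        n_series: int,
        base_theta: CoreParams | None = None,
    ):
        priors.validate()
        self.topology = topology
        self.priors = priors
        self.n_series = n_series
        self.base_theta = base_theta or CoreParams()
        self.core_names = [n for n in CORE_CANDIDATES if n in priors]
        self.core_names += [g for g in topology.active_gains() if g in priors]
        self.peripheral_names = list(PriorSet.PERIPHERAL_NAMES)
        self.n_core = len(self.core_names)
        self.n_phi = len(self.peripheral_names)
        self.dim = self.n_core + self.n_phi * n_series
        self._flat_priors = [priors.require(n) for n in self.core_names]
        self._flat_priors += [
            priors.require(n) for _ in range(n_series) for n in self.peripheral_names
        ]
        self.lower = np.array([p.lower for p in self._flat_priors])
        self.prior_sd = np.array([p.sigma for p in self._flat_priors])
        self.prior_mean = np.array([p.mean() for p in self._flat_priors])
        self._prior_mu = np.array([p.mu for p in self._flat_priors])
        self._prior_const = np.array(
            [-math.log(p.sigma * math.sqrt(2.0 * math.pi)) - p._log_norm
             for p in self._flat_priors]
        )

    def names(self) -> list[str]:
        out = list(self.core_names)
        for i in range(self.n_series):
            out += [f"{n}[{i}]" for n in self.peripheral_names]
        return out

    def unpack(self, x: np.ndarray) -> tuple[CoreParams, list[PeripheralParams]]:
        theta = self.base_theta.replace(
            **{n: float(v) for n, v in zip(self.core_names, x[: self.n_core])}
        )
        # pin gains of absent pathways
        inactive = set(PriorSet.GAIN_NAMES) - set(self.topology.active_gains())
        theta = theta.replace(**{g: 0.0 for g in inactive})
        phis = []
        for i in range(self.n_series):
            block = x[self.n_core + i * self.n_phi: self.n_core + (i + 1) * self.n_phi]
            phis.append(
                PeripheralParams(
                    **{n: float(v) for n, v in zip(self.peripheral_names, block)},
                    A_Z=theta.A_Z0,
                    A_W=theta.A_W0,
                )
            )
        return theta, phis

    def pack(self, theta: CoreParams, phis: list[PeripheralParams]) -> np.ndarray:
        x = [getattr(theta, n) for n in self.core_names]
        for phi in phis:
            x += [getattr(phi, n) for n in self.peripheral_names]
        return np.array(x, dtype=float)

    def log_prior(self, x: np.ndarray) -> float:
        if np.any(x < self.lower):
            return -math.inf
        z = (x - self._prior_mu) / self.prior_sd
        return float(np.sum(self._prior_const - 0.5 * z * z))

    def log_prior_block(self, idx: np.ndarray, sub: np.ndarray) -> float:
        """Prior contribution of one parameter block (for blockwise moves)."""
        if np.any(sub < self.lower[idx]):
            return -math.inf
        z = (sub - self._prior_mu[idx]) / self.prior_sd[idx]
        return float(np.sum(self._prior_const[idx] - 0.5 * z * z))

    def sample_prior(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([float(p.rvs(1, rng)[0]) for p in self._flat_priors])


# ---------------------------------------------------------------------------
# likelihood


def log_prior_density(params: dict, priors: PriorSet) -> float:
    """Sum of log truncated-normal densities over the named parameters."""
    total = 0.0
    for name, value in params.items():
        total += priors.require(name).logpdf(float(value))
        if total == -math.inf:
            break
    return total


def log_likelihood_series(series: MpTimeSeries, trajectory: Trajectory) -> float:
    """Gaussian log likelihood of one series against a model trajectory."""
    if series.sigma_i is None or series.sigma_i <= 0:
        raise ValueError("series needs a positive sigma_i")
    T = series.T_i
    if len(trajectory.V_hat) < T:
        raise ValueError("trajectory does not cover the series grid")
    dv = series.values - trajectory.V_hat[:T]
    s = series.sigma_i
    return float(-T * (_LOG_SQRT2PI + math.log(s)) - 0.5 * np.sum((dv / s) ** 2))


class LikelihoodEngine:
    """Precompiled total-likelihood evaluator for (dataset, topology).

    Batches the latent-state integration across series with the fixed-step
    kernel, then assembles V(t) from the linear amplitude algebra.  Exposes
    both a vector interface (for samplers) and a structured one.
    """

    def __init__(self, dataset: Dataset, topology: ModelTopology, space: ParameterSpace, dt: float = 0.5):
        if any(s.sigma_i is None or s.sigma_i <= 0 for s in dataset.series):
            raise ValueError("every series needs a positive sigma_i")
        self.dataset = dataset
        self.topology = topology
        self.space = space
        self.dt = dt
        self.n = len(dataset)
        self.T_max = max((s.T_i for s in dataset.series), default=1) - 1
        self.T_i = np.array([s.T_i for s in dataset.series], dtype=int)
        self.sigma = dataset.sigmas
        self.values = [s.values for s in dataset.series]
        self.S_inf = np.array([c.effective_smax for c in dataset.conditions])
        self.pkg = np.array([float(c.pkg_active) for c in dataset.conditions])
        self.eta_Cl = np.array([float(c.eta_Cl) for c in dataset.conditions])
        self.eta_Na = np.array([float(c.eta_Na) for c in dataset.conditions])
        self.const_i = -self.T_i * (_LOG_SQRT2PI + np.log(self.sigma))
        self.const = float(np.sum(self.const_i))

    def _series_term(self, i: int, phi: PeripheralParams, cl_row, na_row) -> float:
        T = self.T_i[i]
        v_hat = (
            phi.V_K
            - self.eta_Cl[i] * phi.A_Cl * cl_row[:T]
            + self.eta_Na[i] * phi.A_Na * na_row[:T]
        )
        dv = self.values[i] - v_hat
        return -0.5 * float(np.sum((dv / self.sigma[i]) ** 2)) + self.const_i[i]

    def loglik_terms(self, theta: CoreParams, phis: list[PeripheralParams]) -> np.ndarray:
        """Per-series log-likelihood contributions (one batched integration)."""
        tau = np.array([p.tau_S for p in phis])
        A_Z = np.array([p.A_Z for p in phis])
        A_W = np.array([p.A_W for p in phis])
        cl, na = simulate_grid(
            self.topology, theta, tau, self.S_inf, self.pkg, self.T_max,
            A_Z=A_Z, A_W=A_W, dt=self.dt,
        )
        return np.array(
            [self._series_term(i, phi, cl[i], na[i]) for i, phi in enumerate(phis)]
        )

    def loglik_term_i(self, theta: CoreParams, phi: PeripheralParams, i: int) -> float:
        """Contribution of series i alone (single-series integration)."""
        cl, na = simulate_grid(
            self.topology, theta,
            np.array([phi.tau_S]), self.S_inf[i: i + 1], self.pkg[i: i + 1],
            int(self.T_i[i]) - 1,
            A_Z=np.array([phi.A_Z]), A_W=np.array([phi.A_W]), dt=self.dt,
        )
        return self._series_term(i, phi, cl[0], na[0])

    def loglik_structured(self, theta: CoreParams, phis: list[PeripheralParams]) -> float:
        return float(np.sum(self.loglik_terms(theta, phis)))

    def loglik(self, x: np.ndarray) -> float:
        theta, phis = self.space.unpack(x)
        return self.loglik_structured(theta, phis)


def total_log_likelihood(
    dataset: Dataset,
    topology: ModelTopology,
    theta: CoreParams,
    phi_list: list[PeripheralParams],
    dt: float = 0.5,
) -> float:
    """Sum of per-series Gaussian log likelihoods, each at its own sigma_i."""
    if len(dataset) == 0:
        return 0.0
    if len(phi_list) != len(dataset):
        raise ValueError("need one phi per series")
    space = ParameterSpace(topology, _minimal_priors(), len(dataset), base_theta=theta)
    return LikelihoodEngine(dataset, topology, space, dt=dt).loglik_structured(theta, phi_list)


def _minimal_priors() -> PriorSet:
    from .priors import default_priors

    return default_priors()


# ---------------------------------------------------------------------------
# random-walk Metropolis


@dataclass
class McmcConfig:
    seed: int = 0
    n_steps: int = 4000
    burn_in: int = 1000
    adapt: bool = True
    init_scale: float = 0.1
    target_acceptance: tuple = (0.2, 0.4)
    dt: float = 0.5
    sampler: str = "block"  # "block": Metropolis-within-Gibbs sweeps; "joint": full-vector RW


@dataclass
class Chain:
    samples: np.ndarray
    log_post: np.ndarray
    acceptance_rate: float
    burn_in: int
    seed: int
    space: ParameterSpace | None = None

    def post_burn_in(self) -> np.ndarray:
        return self.samples[self.burn_in:]


def _metropolis(
    log_target,
    x0: np.ndarray,
    lower: np.ndarray,
    scales: np.ndarray,
    n_steps: int,
    burn_in: int,
    rng: np.random.Generator,
    adapt: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Reflective random-walk Metropolis; scale factor adapted in burn-in only."""
    d = len(x0)
    x = np.array(x0, dtype=float)
    lp = log_target(x)
    if not np.isfinite(lp):
        raise ValueError("initial state has zero posterior density")
    factor = 1.0 / math.sqrt(d)
    samples = np.empty((n_steps, d))
    log_posts = np.empty(n_steps)
    accepted = 0
    window_acc = 0
    for step in range(n_steps):
        prop = x + rng.normal(0.0, 1.0, d) * scales * factor
        below = prop < lower
        if np.any(below):  # reflect at the truncation bound (symmetric move)
            prop[below] = 2.0 * lower[below] - prop[below]
        lp_prop = log_target(prop)
        if math.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted += 1
            window_acc += 1
        samples[step] = x
        log_posts[step] = lp
        if adapt and step < burn_in and (step + 1) % 50 == 0:
            rate = window_acc / 50.0
            if rate < 0.2:
                factor *= 0.7
            elif rate > 0.4:
                factor *= 1.4
            window_acc = 0
    return samples, log_posts, accepted / n_steps


def _block_metropolis(
    space: ParameterSpace,
    engine: LikelihoodEngine,
    x0: np.ndarray,
    config: McmcConfig,
    rng: np.random.Generator,
    beta: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Metropolis-within-Gibbs: one core update plus one update per phi block
    per sweep.  A core proposal re-integrates every series; a phi_i proposal
    re-integrates series i only, so sweeps stay cheap while mixing far better
    than full-vector moves in ~70 dimensions.

    beta tempers the likelihood (target = prior x likelihood^beta), which is
    what the evidence ladder needs.  Returns (samples, logliks, log_posts,
    acceptance): logliks are the *untempered* total log likelihoods per sweep.
    """
    nc, nphi, n = space.n_core, space.n_phi, space.n_series
    blocks = [np.arange(nc)] if nc else []
    blocks += [nc + i * nphi + np.arange(nphi) for i in range(n)]
    x = np.array(x0, dtype=float)
    theta, phis = space.unpack(x)
    phis = list(phis)
    terms = engine.loglik_terms(theta, phis)
    lp_prior = space.log_prior(x)
    if not np.isfinite(lp_prior):
        raise ValueError("initial state has zero prior density")
    factors = np.full(len(blocks), 1.0)
    d_block = np.array([len(b) for b in blocks], dtype=float)
    factors /= np.sqrt(d_block)
    samples = np.empty((config.n_steps, space.dim))
    logliks = np.empty(config.n_steps)
    log_posts = np.empty(config.n_steps)
    accepted = np.zeros(len(blocks))
    window = np.zeros(len(blocks))
    tried = np.zeros(len(blocks))
    for step in range(config.n_steps):
        for bi, idx in enumerate(blocks):
            sub = x[idx] + rng.normal(0.0, 1.0, len(idx)) * config.init_scale \
                * space.prior_sd[idx] * factors[bi]
            below = sub < space.lower[idx]
            sub[below] = 2.0 * space.lower[idx][below] - sub[below]  # reflect
            d_prior = space.log_prior_block(idx, sub) - space.log_prior_block(idx, x[idx])
            tried[bi] += 1
            if not np.isfinite(d_prior):
                continue
            core_block = bool(nc) and bi == 0
            if core_block:
                theta_p = _theta_from_core(space, sub)
                terms_p = engine.loglik_terms(theta_p, phis)
                d_ll = float(np.sum(terms_p) - np.sum(terms))
            else:
                i = bi - (1 if nc else 0)
                phi_p = PeripheralParams(
                    **dict(zip(space.peripheral_names, map(float, sub))),
                    A_Z=theta.A_Z0, A_W=theta.A_W0,
                )
                term_p = engine.loglik_term_i(theta, phi_p, i)
                d_ll = term_p - terms[i]
            if math.log(rng.random()) < d_prior + beta * d_ll:
                x[idx] = sub
                lp_prior += d_prior
                if core_block:
                    theta = theta_p
                    terms = terms_p
                else:
                    phis[i] = phi_p
                    terms[i] = term_p
                accepted[bi] += 1
                window[bi] += 1
        samples[step] = x
        logliks[step] = float(np.sum(terms))
        log_posts[step] = lp_prior + beta * logliks[step]
        if config.adapt and step < config.burn_in and (step + 1) % 25 == 0:
            rates = window / 25.0
            factors = np.where(rates < 0.2, factors * 0.7, factors)
            factors = np.where(rates > 0.4, factors * 1.4, factors)
            window[:] = 0.0
    return samples, logliks, log_posts, float(np.sum(accepted) / np.sum(tried))


def sample_posterior(
    dataset: Dataset,
    topology: ModelTopology,
    priors: PriorSet,
    config: McmcConfig | None = None,
    base_theta: CoreParams | None = None,
    x0: np.ndarray | None = None,
) -> Chain:
    """MCMC over the joint (theta, {phi_i}) space targeting prior x likelihood.

    The default block sampler sweeps core and per-series blocks; the "joint"
    sampler is a plain full-vector random walk.  Both reflect proposals at
    truncation bounds and adapt step scales during burn-in only.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    config = config or McmcConfig()
    space = ParameterSpace(topology, priors, len(dataset), base_theta=base_theta)
    engine = LikelihoodEngine(dataset, topology, space, dt=config.dt)
    rng = np.random.default_rng(config.seed)

    if x0 is None:
        x0 = space.prior_mean.copy()
        # start V_K at each series' own mean: a cheap, deterministic warm start
        for i, s in enumerate(dataset.series):
            x0[space.n_core + i * space.n_phi] = float(np.mean(s.values))

    if config.sampler == "block":
        samples, _, log_posts, acc = _block_metropolis(space, engine, x0, config, rng)
    elif config.sampler == "joint":

        def log_target(x):
            lp = space.log_prior(x)
            if not np.isfinite(lp):
                return -math.inf
            return lp + engine.loglik(x)

        samples, log_posts, acc = _metropolis(
            log_target, x0, space.lower, config.init_scale * space.prior_sd,
            config.n_steps, config.burn_in, rng, adapt=config.adapt,
        )
    else:
        raise ValueError(f"unknown sampler {config.sampler!r}")
    if acc < 0.01:
        raise RuntimeError(f"MCMC acceptance rate {acc:.3f} < 1%; chain unusable")
    return Chain(samples, log_posts, acc, config.burn_in, config.seed, space)


def posterior_mean_estimate(chain: Chain) -> tuple[CoreParams, list[PeripheralParams]]:
    """Posterior-mean point estimate (the paper's 'mean a posteriori')."""
    kept = chain.post_burn_in()
    if len(kept) == 0:
        raise ValueError("empty chain after burn-in")
    mean = kept.mean(axis=0)
    if chain.space is None:
        raise ValueError("chain carries no parameter space")
    return chain.space.unpack(mean)


# ---------------------------------------------------------------------------
# evidence by stepping-stone sampling


@dataclass
class EvidenceConfig:
    n_rungs: int = 8
    schedule_power: float = 5.0
    samples_per_rung: int = 2000
    burn_in_per_rung: int = 200
    seed: int = 0
    init_scale: float = 0.1
    dt: float = 0.5


@dataclass
class EvidenceResult:
    topology_index: int
    log_evidence: float
    mc_standard_error: float
    n_rungs: int
    samples_per_rung: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "topology_index": self.topology_index,
            "log_evidence": self.log_evidence,
            "mc_standard_error": self.mc_standard_error,
            "n_rungs": self.n_rungs,
            "samples_per_rung": self.samples_per_rung,
            "seed": self.seed,
        }


@dataclass
class VectorProblem:
    """Generic target for the evidence estimator: prior x likelihood on R^d."""

    log_prior: callable
    log_likelihood: callable
    sample_prior: callable  # (rng) -> vector
    lower: np.ndarray
    scales: np.ndarray


def stepping_stone(
    problem: VectorProblem,
    config: EvidenceConfig,
) -> tuple[float, float]:
    """Stepping-stone estimate of ln(evidence) with a blocked MC standard error.

    Ladder beta_k = (k/K)^p, k = 0..K.  Rung 0 uses exact iid prior draws; each
    later rung continues a Metropolis chain targeting prior x likelihood^beta.
    """
    K = config.n_rungs
    rng = np.random.default_rng(config.seed)
    betas = (np.arange(K + 1) / K) ** config.schedule_power
    N = config.samples_per_rung

    # rung 0: iid prior samples
    xs = np.stack([problem.sample_prior(rng) for _ in range(N)])
    lls = np.array([problem.log_likelihood(x) for x in xs])

    log_e = 0.0
    var_total = 0.0
    x_state = xs[int(np.argmax(lls))]
    for k in range(1, K + 1):
        d_beta = betas[k] - betas[k - 1]
        terms = d_beta * lls
        log_rk = logsumexp(terms) - math.log(N)
        log_e += float(log_rk)
        # blocked standard error on the log-ratio (delta method on batch means)
        B = min(20, N)
        batch = np.array_split(terms, B)
        batch_log = np.array([logsumexp(b) - math.log(len(b)) for b in batch])
        var_total += float(np.var(batch_log, ddof=1) / B) if B > 1 else 0.0

        if k == K:
            break
        beta = betas[k]

        def log_target(x, _b=beta):
            lp = problem.log_prior(x)
            if not np.isfinite(lp):
                return -math.inf
            return lp + _b * problem.log_likelihood(x)

        n_steps = N + config.burn_in_per_rung
        samples, _, _ = _metropolis(
            log_target, x_state, problem.lower,
            config.init_scale * problem.scales,
            n_steps, config.burn_in_per_rung, rng, adapt=True,
        )
        xs = samples[config.burn_in_per_rung:]
        lls = np.array([problem.log_likelihood(x) for x in xs])
        x_state = xs[-1]
    return log_e, math.sqrt(var_total)


def _rung_contribution(terms, d_beta, N):
    log_rk = logsumexp(d_beta * terms) - math.log(N)
    B = min(20, N)
    batch = np.array_split(d_beta * terms, B)
    batch_log = np.array([logsumexp(b) - math.log(len(b)) for b in batch])
    var = float(np.var(batch_log, ddof=1) / B) if B > 1 else 0.0
    return float(log_rk), var


def estimate_log_evidence(
    dataset: Dataset,
    topology: ModelTopology,
    priors: PriorSet,
    config: EvidenceConfig | None = None,
    base_theta: CoreParams | None = None,
) -> EvidenceResult:
    """ln E(V, M) by stepping-stone sampling; ln E = 0 for an empty dataset.

    Rung 0 draws iid from the (factorized truncated-normal) prior; every later
    rung continues a tempered block-Metropolis chain, which mixes far better
    than full-vector moves in the joint (theta, {phi_i}) space.
    """
    config = config or EvidenceConfig()
    if len(dataset) == 0:
        return EvidenceResult(topology.index, 0.0, 0.0, config.n_rungs,
                              config.samples_per_rung, config.seed)
    space = ParameterSpace(topology, priors, len(dataset), base_theta=base_theta)
    engine = LikelihoodEngine(dataset, topology, space, dt=config.dt)
    rng = np.random.default_rng(config.seed)
    K = config.n_rungs
    N = config.samples_per_rung
    betas = (np.arange(K + 1) / K) ** config.schedule_power

    xs = np.stack([space.sample_prior(rng) for _ in range(N)])
    lls = np.array([engine.loglik(x) for x in xs])
    x_state = xs[int(np.argmax(lls))]

    log_e = 0.0
    var_total = 0.0
    for k in range(1, K + 1):
        log_rk, var = _rung_contribution(lls, betas[k] - betas[k - 1], N)
        log_e += log_rk
        var_total += var
        if k == K:
            break
        mcfg = McmcConfig(
            seed=config.seed + k, n_steps=N + config.burn_in_per_rung,
            burn_in=config.burn_in_per_rung, init_scale=config.init_scale,
            dt=config.dt,
        )
        samples, logliks, _, _ = _block_metropolis(
            space, engine, x_state, mcfg, rng, beta=float(betas[k])
        )
        lls = logliks[config.burn_in_per_rung:]
        x_state = samples[-1]
    return EvidenceResult(topology.index, log_e, math.sqrt(var_total),
                          config.n_rungs, config.samples_per_rung, config.seed)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting (profile strategy)
#
# For fixed core theta and fixed tau_S, V(t) is linear in (V_K, A_Cl, A_Na),
# so the inner problem per series is a tiny sign-constrained least-squares
# solve over a grid of tau_S candidates; the outer derivative-free search then
# runs over the low-dimensional core vector only.


@dataclass
class OptConfig:
    seed: int = 0
    n_starts: int = 3
    maxiter: int = 250
    tau_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(3.0, 150.0, 25)
    )
    dt: float = 0.5
    # MAP-style penalized fitting by default: the study's point estimates are
    # posterior-flavored everywhere; set False for pure maximum likelihood
    # (AIC/BIC comparisons)
    include_prior: bool = True


@dataclass
class FitResult:
    topology_index: int
    theta_est: CoreParams
    phi_est: list[PeripheralParams]
    log_likelihood_total: float
    diagnostics: dict = field(default_factory=dict)


def _amplitude_profile(v, cl_cols, na_cols, ridge=None):
    """Sign-constrained amplitude fit, batched over tau_S candidates.

    Minimizes ||v - (V_K - a*cl + b*na)||^2 over free V_K and a, b >= 0 for
    every candidate column pair at once.  With only two constrained
    coefficients the KKT cases (both free / a=0 / b=0 / both zero) can be
    enumerated exactly.  Either column block may be None (blocked channel).

    ridge, if given, is (mu_a, sd_a, mu_b, sd_b, sigma): Gaussian priors on
    the amplitudes (MAP profiling); the returned objective is then the SSE
    plus 2*sigma^2 times the prior quadratic, so downstream ``obj/(2 sigma^2)``
    comparisons remain valid.  Returns arrays (obj, V_K, a, b) per candidate.
    """
    n_tau = len(cl_cols) if cl_cols is not None else len(na_cols)
    Y = v - v.mean()
    yy = float(Y @ Y)
    zeros = np.zeros(n_tau)

    if ridge is None:
        la = lb = 0.0
        mu_a = mu_b = 0.0
    else:
        mu_a, sd_a, mu_b, sd_b, sigma = ridge
        la = sigma * sigma / (sd_a * sd_a)
        lb = sigma * sigma / (sd_b * sd_b)

    def centered(cols):
        return cols - cols.mean(axis=1, keepdims=True)

    if cl_cols is None and na_cols is None:
        return np.full(n_tau, yy), np.full(n_tau, v.mean()), zeros, zeros

    C = centered(cl_cols) if cl_cols is not None else None
    N = centered(na_cols) if na_cols is not None else None
    cc = np.einsum("jt,jt->j", C, C) if C is not None else None
    nn = np.einsum("jt,jt->j", N, N) if N is not None else None
    cy = C @ Y if C is not None else None
    ny = N @ Y if N is not None else None
    cn = (np.einsum("jt,jt->j", C, N)
          if C is not None and N is not None else None)

    def obj_of(a, b):
        out = np.full(n_tau, yy)
        if C is not None:
            out += a * a * cc + 2.0 * a * cy + la * (a - mu_a) ** 2
        if N is not None:
            out += b * b * nn - 2.0 * b * ny + lb * (b - mu_b) ** 2
        if cn is not None:
            out -= 2.0 * a * b * cn
        return out

    candidates = [(zeros, zeros)]
    if C is not None:
        denom = cc + la
        a1 = np.maximum(0.0, (-cy + la * mu_a) / np.where(denom > 0, denom, 1.0))
        candidates.append((np.where(denom > 0, a1, 0.0), zeros))
    if N is not None:
        denom = nn + lb
        b1 = np.maximum(0.0, (ny + lb * mu_b) / np.where(denom > 0, denom, 1.0))
        candidates.append((zeros, np.where(denom > 0, b1, 0.0)))
    if cn is not None:
        A11 = cc + la
        A22 = nn + lb
        det = A11 * A22 - cn * cn
        ok = det > 1e-12
        safe_det = np.where(ok, det, 1.0)
        r1 = -cy + la * mu_a
        r2 = ny + lb * mu_b
        a2 = (r1 * A22 + cn * r2) / safe_det
        b2 = (r2 * A11 + cn * r1) / safe_det
        feas = ok & (a2 >= 0) & (b2 >= 0)
        candidates.append((np.where(feas, a2, 0.0), np.where(feas, b2, 0.0)))

    obj_best = None
    for a, b in candidates:
        obj = obj_of(a, b)
        if obj_best is None:
            obj_best, a_best, b_best = obj, a, b
        else:
            better = obj < obj_best
            obj_best = np.where(better, obj, obj_best)
            a_best = np.where(better, a, a_best)
            b_best = np.where(better, b, b_best)

    vk = v.mean()
    if cl_cols is not None:
        vk = vk + a_best * cl_cols.mean(axis=1)
    if na_cols is not None:
        vk = vk - b_best * na_cols.mean(axis=1)
    return obj_best, vk, a_best, b_best


def _profile_peripherals(
    engine: LikelihoodEngine,
    theta: CoreParams,
    tau_grid: np.ndarray,
    include_prior: bool = False,
):
    """Best (phi_i per series, total loglik) for fixed theta, tau_S on a grid.

    One batched integration per unique (S_inf, pkg) condition pair covers all
    series and all tau_S candidates; amplitudes and V_K are profiled out by
    exact constrained least squares.  With include_prior the per-series
    selection maximizes likelihood x prior over (tau_S, A_Cl, A_Na) — MAP
    profiling — while the returned total is always the pure log likelihood.
    """
    n_tau = len(tau_grid)
    keys = list(zip(engine.S_inf, engine.pkg))
    basis: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for key in set(keys):
        S_inf = np.full(n_tau, key[0])
        pkg = np.full(n_tau, key[1])
        basis[key] = simulate_grid(
            engine.topology, theta, tau_grid, S_inf, pkg, engine.T_max, dt=engine.dt
        )
    priors = engine.space.priors
    p_a, p_b = priors.require("A_Cl"), priors.require("A_Na")
    p_tau, p_vk = priors.require("tau_S"), priors.require("V_K")
    tau_logp = np.array([p_tau.logpdf(float(t)) for t in tau_grid])
    phis = []
    loglik = engine.const
    phi_logprior = 0.0
    for i in range(engine.n):
        cl_all, na_all = basis[keys[i]]
        T = engine.T_i[i]
        v = engine.values[i]
        s2 = engine.sigma[i] ** 2
        ridge = (
            (p_a.mu, p_a.sigma, p_b.mu, p_b.sigma, engine.sigma[i])
            if include_prior else None
        )
        obj, vk, a, b = _amplitude_profile(
            v,
            cl_all[:, :T] if engine.eta_Cl[i] else None,
            na_all[:, :T] if engine.eta_Na[i] else None,
            ridge=ridge,
        )
        crit = obj / (2.0 * s2)
        if include_prior:
            crit = crit - tau_logp
        j = int(np.argmin(crit))
        sse = float(obj[j])
        if include_prior:  # strip the ridge terms to recover the pure SSE
            if engine.eta_Cl[i]:
                sse -= s2 / p_a.sigma ** 2 * (a[j] - p_a.mu) ** 2
            if engine.eta_Na[i]:
                sse -= s2 / p_b.sigma ** 2 * (b[j] - p_b.mu) ** 2
        phi_logprior += float(tau_logp[j])
        if engine.eta_Cl[i]:
            phi_logprior += p_a.logpdf(float(a[j]))
        if engine.eta_Na[i]:
            phi_logprior += p_b.logpdf(float(b[j]))
        phi_logprior += p_vk.logpdf(float(vk[j]))
        phis.append(
            PeripheralParams(
                V_K=float(vk[j]),
                tau_S=float(tau_grid[j]),
                A_Cl=float(a[j]) if engine.eta_Cl[i] else p_a.mean(),
                A_Na=float(b[j]) if engine.eta_Na[i] else p_b.mean(),
                A_Z=theta.A_Z0,
                A_W=theta.A_W0,
            )
        )
        loglik -= 0.5 * sse / s2
    return phis, loglik, phi_logprior


def maximize_log_likelihood(
    dataset: Dataset,
    topology: ModelTopology,
    priors: PriorSet,
    config: OptConfig | None = None,
    base_theta: CoreParams | None = None,
) -> FitResult:
    """Multi-start profile maximization of the total log likelihood.

    Outer derivative-free search over the core vector; peripherals are
    profiled out exactly (linear algebra) up to the tau_S grid resolution.
    Deterministic for a given seed.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    config = config or OptConfig()
    space = ParameterSpace(topology, priors, len(dataset), base_theta=base_theta)
    engine = LikelihoodEngine(dataset, topology, space, dt=config.dt)
    rng = np.random.default_rng(config.seed)

    core_priors = [priors.require(n) for n in space.core_names]
    lb = np.array([p.lower for p in core_priors])
    ub = np.array([p.mu + 10.0 * p.sigma for p in core_priors])

    # search over u with x = lower + exp(u): scale parameters (Hill constants,
    # gains) live on ratio scales, and the transform keeps bounds implicit
    eps = 1e-3

    def to_x(u):
        return lb + np.exp(u)

    def to_u(x):
        return np.log(np.maximum(x - lb, eps))

    def negloglik_u(u):
        theta = _theta_from_core(space, to_x(u))
        _, ll, phi_lp = _profile_peripherals(engine, theta, config.tau_grid,
                                             include_prior=config.include_prior)
        if config.include_prior:
            ll += phi_lp
            ll += sum(p.logpdf(float(v)) for p, v in zip(core_priors, to_x(u)))
        if not np.isfinite(ll):
            return 1e12
        return -ll

    starts = [np.array([max(p.mean(), p.lower + 0.3 * p.sigma) for p in core_priors])]
    for _ in range(config.n_starts - 1):
        starts.append(
            np.array([max(float(p.rvs(1, rng)[0]), p.lower + eps) for p in core_priors])
        )

    best = None
    for x0 in starts:
        if space.n_core == 0:
            best = (negloglik_u(np.empty(0)), np.empty(0))
            break
        res = minimize(
            negloglik_u, to_u(np.clip(x0, lb + eps, ub)), method="Nelder-Mead",
            bounds=list(zip(to_u(lb + np.full_like(lb, eps)), to_u(ub))),
            options={"maxiter": config.maxiter, "xatol": 1e-3, "fatol": 1e-6},
        )
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x)
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError("no optimizer start converged")
    theta = _theta_from_core(space, to_x(best[1]))
    phis, ll, _ = _profile_peripherals(engine, theta, config.tau_grid,
                                       include_prior=config.include_prior)
    return FitResult(
        topology_index=topology.index,
        theta_est=theta,
        phi_est=phis,
        log_likelihood_total=float(ll),
        diagnostics={"seed": config.seed, "n_starts": config.n_starts,
                     "neg_loglik": float(best[0])},
    )


def _theta_from_core(space: ParameterSpace, core_vec: np.ndarray) -> CoreParams:
    theta = space.base_theta.replace(
        **{n: float(v) for n, v in zip(space.core_names, core_vec)}
    )
    inactive = set(PriorSet.GAIN_NAMES) - set(space.topology.active_gains())
    return theta.replace(**{g: 0.0 for g in inactive})


def fit_peripherals(
    series: MpTimeSeries,
    condition: ConditionParams,
    topology: ModelTopology,
    theta: CoreParams,
    priors: PriorSet,
    tau_grid: np.ndarray | None = None,
    dt: float = 0.5,
    include_prior: bool = True,
) -> tuple[PeripheralParams, float]:
    """Best phi for one series with the core frozen; returns (phi, loglik).

    MAP profiling by default (the study always uses MAP-style point values for
    per-cell parameters); the returned loglik is the pure likelihood.
    """
    tau_grid = tau_grid if tau_grid is not None else np.geomspace(3.0, 150.0, 25)
    ds = Dataset(series=[series], conditions=[condition])
    space = ParameterSpace(topology, priors, 1, base_theta=theta)
    engine = LikelihoodEngine(ds, topology, space, dt=dt)
    phis, ll, _ = _profile_peripherals(engine, theta, tau_grid,
                                       include_prior=include_prior)
    return phis[0], float(ll)


def information_criteria(fit: FitResult, k_params: int, n_points: int) -> tuple[float, float]:
    """(AIC, BIC) from a maximum-likelihood fit."""
    if k_params < 0 or n_points < 1:
        raise ValueError("k_params must be >= 0 and n_points >= 1")
    ll = fit.log_likelihood_total
    return 2.0 * k_params - 2.0 * ll, k_params * math.log(n_points) - 2.0 * ll
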