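"""Approximate Bayesian computation — sequential Monte Carlo (ABC-SMC).

Likelihood-free posterior approximation through a weighted particle
population refined over generations: generation 0 draws from independent
uniform priors with equal weights; each later generation sets its acceptance
threshold epsilon to the weighted median of the previous generation's
distances, proposes by sampling a particle proportionally to weight and
perturbing it with a multivariate-normal KDE kernel (weighted-covariance
bandwidth with Silverman scaling), rejects proposals outside the prior
support, and re-weights accepted particles by prior density over the KDE
mixture density.  The distance is the root-mean-square error between the
predicted and observed tag-level glycoprofiles, on the percent scale, with
both protein entities concatenated into one vector.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PriorSpec",
    "ParticlePopulation",
    "PosteriorSummary",
    "rmse",
    "weighted_quantile",
    "abc_smc",
    "map_estimate",
    "credible_interval",
    "summarize",
]


@dataclass
class PriorSpec:
    """Independent uniform priors: parameter names and (lo, hi) bounds."""

    names: list
    bounds: list  # [(lo, hi), ...]

    def __post_init__(self):
        if len(self.names) != len(self.bounds):
            raise ValueError("names and bounds must have equal length")
        for name, (lo, hi) in zip(self.names, self.bounds):
            if not lo < hi:
                raise ValueError(f"prior for {name!r} needs lo < hi, got ({lo}, {hi})")
        self.lo = np.array([b[0] for b in self.bounds], dtype=float)
        self.hi = np.array([b[1] for b in self.bounds], dtype=float)

    @property
    def dim(self) -> int:
        return len(self.names)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=(n, self.dim))

    def contains(self, theta: np.ndarray) -> bool:
        return bool(np.all(theta >= self.lo) and np.all(theta <= self.hi))

    def log_pdf(self, theta: np.ndarray) -> float:
        if not self.contains(theta):
            return -np.inf
        return -float(np.sum(np.log(self.hi - self.lo)))


@dataclass
class ParticlePopulation:
    """Weighted parameter samples with distances; the SMC state per generation."""

    particles: np.ndarray  # (n, dim)
    weights: np.ndarray  # (n,), sums to 1
    distances: np.ndarray  # (n,)
    epsilon: float
    generation: int
    n_attempts: int = 0
    names: list = field(default_factory=list)


@dataclass
class PosteriorSummary:
    """MAP estimate and per-parameter 95% credible intervals."""

    names: list
    map_estimate: np.ndarray
    cri_95: list  # [(lo, hi), ...]
    population: ParticlePopulation


def rmse(pred: dict, obs: dict) -> float:
    """Root-mean-square error between profiles on the percent scale.

    Profiles are ``entity -> {tag: percent}``; the error is evaluated on the
    observed support with missing predicted tags treated as 0, concatenating
    all entities into one vector.
    """
    diffs = []
    for entity in sorted(obs):
        pred_entity = pred.get(entity, {})
        for tag in sorted(obs[entity]):
            diffs.append(pred_entity.get(tag, 0.0) - obs[entity][tag])
    if not diffs:
        raise ValueError("empty profile support")
    arr = np.asarray(diffs)
    return float(np.sqrt(np.mean(arr * arr)))


def weighted_quantile(values, weights, q):
    """Weighted quantile with linear interpolation.

    Reduces to numpy's default (linear) quantile for equal weights: sorted
    points sit at positions C_{k-1} / C_{n-1} of the exclusive cumulative
    weight, and quantiles interpolate linearly between them.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 1:
        return float(values[0]) if np.isscalar(q) else np.full_like(
            np.asarray(q, dtype=float), float(values[0])
        )
    order = np.argsort(values, kind="stable")
    xs = values[order]
    ws = weights[order] / weights.sum()
    cumulative = np.cumsum(ws)
    positions = cumulative - ws  # exclusive cumulative weight
    if positions[-1] <= 0:  # all weight on the last particle
        return xs[-1]
    positions = positions / positions[-1]
    return np.interp(q, positions, xs)


def _weighted_covariance(particles: np.ndarray, weights: np.ndarray) -> np.ndarray:
    n, dim = particles.shape
    if n == 1:
        return np.eye(dim) * 1e-12
    cov = np.atleast_2d(np.cov(particles.T, aweights=weights))
    # regularise degenerate directions
    jitter = 1e-12 * max(np.trace(cov) / dim, 1e-12)
    return cov + jitter * np.eye(dim)


def _transition_covariance(particles: np.ndarray, weights: np.ndarray, bw_factor: float) -> np.ndarray:
    """Proposal-kernel covariance: the full weighted-sample covariance.

    Using the unshrunk covariance (as multivariate-normal ABC transitions
    conventionally do) keeps proposals dispersed enough at small population
    sizes; a Silverman-shrunk kernel under-disperses and biases the posterior
    approximation.  ``bw_factor`` rescales the kernel if desired.
    """
    return bw_factor**2 * _weighted_covariance(particles, weights)


def _kde_covariance(particles: np.ndarray, weights: np.ndarray, bw_factor: float) -> np.ndarray:
    """Density-estimation bandwidth: weighted covariance with Silverman scaling."""
    n, dim = particles.shape
    if n == 1:
        return np.eye(dim) * 1e-12
    n_eff = 1.0 / float(np.sum(weights**2))
    silverman = (4.0 / (n_eff * (dim + 2.0))) ** (2.0 / (dim + 4.0))
    return bw_factor**2 * silverman * _weighted_covariance(particles, weights)


def _mvn_log_density(delta: np.ndarray, chol: np.ndarray) -> np.ndarray:
    """Log N(delta; 0, LL^T) for rows of delta."""
    dim = delta.shape[1]
    z = np.linalg.solve(chol, delta.T).T
    log_det = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (np.sum(z * z, axis=1) + dim * math.log(2 * math.pi) + log_det)


def abc_smc(
    prior: PriorSpec,
    simulator,
    observed: dict,
    *,
    n: int = 200,
    max_generations: int = 25,
    eps_min: float = 0.0,
    seed: int = 0,
    bw_factor: float = 1.0,
    distance=rmse,
    max_attempts_per_particle: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[ParticlePopulation]:
    """Run ABC-SMC and return the per-generation populations.

    ``simulator`` maps a parameter vector to a predicted profile dict, or
    ``None`` when the forward model fails to converge for that draw (such
    draws are rejected and counted, never fatal).  Termination: after
    ``max_generations`` generations or once epsilon falls to ``eps_min``.
    Fully deterministic given the seed.
    """
    if n < 2:
        raise ValueError("population size n must be >= 2")
    rng = np.random.default_rng(seed) if rng is None else rng
    dim = prior.dim

    # generation 0: accept-all draws from the prior (epsilon_0 = inf)
    particles = np.empty((n, dim))
    distances = np.empty(n)
    attempts = 0
    filled = 0
    while filled < n:
        attempts += 1
        if attempts > max_attempts_per_particle * n:
            raise RuntimeError("prior predictive simulation keeps failing")
        theta = prior.sample(rng, 1)[0]
        pred = simulator(theta)
        if pred is None:
            continue
        particles[filled] = theta
        distances[filled] = distance(pred, observed)
        filled += 1
    population = ParticlePopulation(
        particles=particles,
        weights=np.full(n, 1.0 / n),
        distances=distances,
        epsilon=np.inf,
        generation=0,
        n_attempts=attempts,
        names=list(prior.names),
    )
    populations = [population]

    for generation in range(1, max_generations):
        prev = populations[-1]
        epsilon = float(weighted_quantile(prev.distances, prev.weights, 0.5))
        if epsilon <= eps_min:
            break
        cov = _transition_covariance(prev.particles, prev.weights, bw_factor)
        chol = np.linalg.cholesky(cov)

        new_particles = np.empty((n, dim))
        new_distances = np.empty(n)
        new_weights = np.empty(n)
        attempts = 0
        filled = 0
        stalled = False
        while filled < n:
            attempts += 1
            if attempts > max_attempts_per_particle * n:
                stalled = True
                break
            pick = rng.choice(n, p=prev.weights)
            theta = prev.particles[pick] + chol @ rng.standard_normal(dim)
            if not prior.contains(theta):
                continue
            pred = simulator(theta)
            if pred is None:
                continue
            dist = distance(pred, observed)
            if dist > epsilon:
                continue
            log_kernel = _mvn_log_density(theta[None, :] - prev.particles, chol)
            mixture = np.sum(prev.weights * np.exp(log_kernel))
            new_particles[filled] = theta
            new_distances[filled] = dist
            new_weights[filled] = math.exp(prior.log_pdf(theta)) / max(mixture, 1e-300)
            filled += 1
        if stalled:
            warnings.warn(
                f"acceptance stalled in generation {generation} after "
                f"{attempts} attempts ({filled}/{n} accepted)",
                stacklevel=2,
            )
            if filled < 2:
                break
            new_particles = new_particles[:filled]
            new_distances = new_distances[:filled]
            new_weights = new_weights[:filled]
        new_weights = new_weights / new_weights.sum()
        populations.append(
            ParticlePopulation(
                particles=new_particles,
                weights=new_weights,
                distances=new_distances,
                epsilon=epsilon,
                generation=generation,
                n_attempts=attempts,
                names=list(prior.names),
            )
        )
        if stalled:
            break
    return populations


def map_estimate(population: ParticlePopulation, bw_factor: float = 1.0) -> np.ndarray:
    """Particle maximising the weighted KDE density at particle locations."""
    particles = population.particles
    weights = population.weights
    if len(particles) == 1:
        warnings.warn("single-particle population; MAP is that particle", stacklevel=2)
        return particles[0].copy()
    cov = _kde_covariance(particles, weights, bw_factor)
    chol = np.linalg.cholesky(cov)
    densities = np.empty(len(particles))
    for i, theta in enumerate(particles):
        log_kernel = _mvn_log_density(theta[None, :] - particles, chol)
        densities[i] = float(np.sum(weights * np.exp(log_kernel)))
    return particles[int(np.argmax(densities))].copy()


def credible_interval(population: ParticlePopulation, level: float = 0.95) -> list:
    """Per-parameter weighted-quantile credible intervals."""
    alpha = (1.0 - level) / 2.0
    out = []
    for k in range(population.particles.shape[1]):
        lo = float(weighted_quantile(population.particles[:, k], population.weights, alpha))
        hi = float(
            weighted_quantile(population.particles[:, k], population.weights, 1.0 - alpha)
        )
        out.append((lo, hi))
    return out


def summarize(population: ParticlePopulation, bw_factor: float = 1.0) -> PosteriorSummary:
    return PosteriorSummary(
        names=list(population.names),
        map_estimate=map_estimate(population, bw_factor),
        cri_95=credible_interval(population),
        population=population,
    )
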