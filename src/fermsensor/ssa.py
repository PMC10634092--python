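"""Sparrow search algorithm (SSA) with hybrid Cauchy-Gaussian mutation.

SSA is a population metaheuristic mimicking a foraging sparrow flock with
three roles per generation:

* discoverers (a pd_frac fraction, the fittest birds) either exploit —
  shrinking multiplicatively toward the origin of their current position —
  when the alarm value r stays below the safety threshold beta, or take a
  Gaussian-perturbed step when danger is signalled;
* followers either jump toward the best discoverer (better-ranked half)
  or scatter away from the worst position (worse-ranked half);
* a random sd_frac of scouts react to danger: birds away from the global
  best move toward it, birds sitting at the best move relative to the
  worst, scaled by 1/(f_i - f_worst + eps).

The hybrid mutation (the "I" in ISSA) perturbs the incumbent best once per
generation with a mixture of a standard Cauchy and a standard Gaussian
draw whose mixing weights follow the iteration schedule
lambda1 = 1 - t^2/T^2, lambda2 = t^2/T^2 (heavy-tailed exploration early,
fine-grained exploitation late); the mutant replaces the best only if it
improves fitness, so the trajectory can never worsen.

The printed update rules circulating for this algorithm family are often
typographically garbled; this implementation follows the canonical role
structure above and documents its reading in docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SSAConfig:
    n: int = 20                  # population size
    pd_frac: float = 0.2         # discoverer fraction
    sd_frac: float = 0.1         # scout (early-warning) fraction
    safety_threshold: float = 0.8
    T: int = 30                  # generations
    bounds: tuple = ((0.0, 1.0),)
    seed: int = 0
    mutate: bool = True          # hybrid Cauchy-Gaussian mutation on/off
    mutate_followers: bool = False  # mutate each follower instead of the best
    eps: float = 1e-12

    def __post_init__(self):
        if not (0 < self.pd_frac < 1 and 0 < self.sd_frac < 1):
            raise ValueError("pd_frac and sd_frac must lie in (0, 1)")
        if not 0 < self.safety_threshold < 1:
            raise ValueError("safety_threshold must lie in (0, 1)")
        if self.T < 1 or self.n < 2:
            raise ValueError("need T >= 1 and n >= 2")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("each bound must satisfy low < high")

    @property
    def dim(self) -> int:
        return len(self.bounds)

    def clip(self, x: np.ndarray) -> np.ndarray:
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(x, lo, hi)


@dataclass
class SSAState:
    positions: np.ndarray
    fitnesses: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    history: list = field(default_factory=list)
    t: int = 0


def _safe_eval(fitness, x) -> float:
    val = float(fitness(np.asarray(x, float)))
    if not np.isfinite(val):
        warnings.warn("non-finite fitness treated as +inf", stacklevel=3)
        return np.inf
    return val


def init_population(config: SSAConfig, fitness, rng=None) -> SSAState:
    """Uniform random population within bounds, fitness evaluated once."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    pos = rng.uniform(lo, hi, size=(config.n, config.dim))
    fit = np.array([_safe_eval(fitness, p) for p in pos])
    best = int(np.argmin(fit))
    state = SSAState(positions=pos, fitnesses=fit,
                     best_position=pos[best].copy(),
                     best_fitness=float(fit[best]))
    state.history.append(state.best_fitness)
    return state


def ssa_iterate(state: SSAState, config: SSAConfig, fitness, rng) -> SSAState:
    """One SSA generation: discoverers, followers, scouts, greedy elitism."""
    n, d = state.positions.shape
    pos = state.positions.copy()
    fit = state.fitnesses.copy()
    order = np.argsort(fit, kind="stable")           # best first
    n_pd = max(1, int(round(config.pd_frac * n)))
    t_cur = state.t + 1

    r_alarm = rng.random()                            # alarm value, per generation
    for rank, i in enumerate(order[:n_pd]):
        if r_alarm < config.safety_threshold:
            # exploit: multiplicative shrink, stronger for lower-ranked birds
            pos[i] = pos[i] * np.exp(-(rank + 1) / (rng.random() * config.T
                                                    + config.eps))
        else:
            pos[i] = pos[i] + rng.standard_normal() * np.ones(d)

    best_disc = pos[order[0]]
    worst = state.positions[int(np.argmax(fit))]
    for rank, i in enumerate(order[n_pd:], start=n_pd):
        if rank >= n / 2:
            # starved follower scatters away from the worst position
            q = rng.standard_normal()
            pos[i] = q * np.exp((worst - pos[i]) / ((rank + 1) ** 2))
        else:
            # follower forages around the best discoverer
            a = rng.choice([-1.0, 1.0], size=d)
            pos[i] = best_disc + np.abs(pos[i] - best_disc) @ a[:, None] @ \
                np.atleast_2d(a) / d

    n_sd = max(1, int(round(config.sd_frac * n)))
    scouts = rng.choice(n, size=n_sd, replace=False)
    f_best, f_worst = fit.min(), fit.max()
    for i in scouts:
        if fit[i] > f_best:
            rho = rng.standard_normal()
            pos[i] = state.best_position + rho * np.abs(pos[i] - state.best_position)
        else:
            k = rng.uniform(-1, 1)
            pos[i] = pos[i] + k * (np.abs(pos[i] - worst)
                                   / (fit[i] - f_worst + config.eps))

    pos = config.clip(pos)
    new_fit = np.array([_safe_eval(fitness, p) for p in pos])
    state.positions = pos
    state.fitnesses = new_fit
    # greedy elitism: the incumbent best survives outside the population
    b = int(np.argmin(new_fit))
    if new_fit[b] < state.best_fitness:
        state.best_fitness = float(new_fit[b])
        state.best_position = pos[b].copy()
    state.t = t_cur
    return state


def hybrid_mutation(best: np.ndarray, t: int, T: int, rng) -> np.ndarray:
    """Cauchy-Gaussian mutant of the best position.

    x' = x_best * (1 + lambda1*Cauchy(0,1) + lambda2*Gauss(0,1)) with
    lambda1 = 1 - t^2/T^2 and lambda2 = t^2/T^2.
    """
    if T == 0:
        raise ValueError("T must be >= 1")
    lam2 = (t / T) ** 2
    lam1 = 1.0 - lam2
    cauchy = rng.standard_cauchy()
    gauss = rng.standard_normal()
    return np.asarray(best, float) * (1.0 + lam1 * cauchy + lam2 * gauss)


def optimize(fitness, config: SSAConfig):
    """Run T generations of (I)SSA; returns (best_position, history).

    ``history`` has T+1 entries (initial population included) and is
    non-increasing.  The mutation step uses its own RNG stream so that
    disabling it leaves the base SSA trajectory untouched.
    """
    root = np.random.SeedSequence(config.seed)
    rng, rng_mut = [np.random.default_rng(s) for s in root.spawn(2)]
    try:
        state = init_population(config, fitness, rng)
    except Exception as exc:
        raise RuntimeError(f"fitness evaluation failed at init: {exc}") from exc
    if not np.any(np.isfinite(state.fitnesses)):
        raise RuntimeError("fitness returned non-finite values for the whole "
                           "initial population")
    for _ in range(config.T):
        state = ssa_iterate(state, config, fitness, rng)
        if config.mutate:
            if config.mutate_followers:
                order = np.argsort(state.fitnesses, kind="stable")
                n_pd = max(1, int(round(config.pd_frac * config.n)))
                targets = order[n_pd:]
            else:
                targets = [None]                      # mutate the global best
            for i in targets:
                base = state.best_position if i is None else state.positions[i]
                cand = config.clip(hybrid_mutation(base, state.t, config.T,
                                                   rng_mut))
                f = _safe_eval(fitness, cand)
                if i is None:
                    if f < state.best_fitness:
                        state.best_fitness = float(f)
                        state.best_position = cand.copy()
                elif f < state.fitnesses[i]:
                    state.fitnesses[i] = f
                    state.positions[i] = cand
                    if f < state.best_fitness:
                        state.best_fitness = float(f)
                        state.best_position = cand.copy()
        state.history.append(state.best_fitness)
    return state.best_position.copy(), np.array(state.history)
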