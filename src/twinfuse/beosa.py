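"""Binary Ebola optimization search algorithm (BEOSA).

A population metaheuristic over {0, 1}^dim used here for two selection
problems: choosing feature columns (wrapper fitness with a k-NN classifier)
and choosing probability maps at the fusion layer.  Candidate solutions keep
a continuous "shadow" position that is re-binarized every update through an
S- or V-shaped transfer function; an epidemiological bookkeeping rule decides
which individuals ("infected") are perturbed each iteration.

Fitness is minimized throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BinaryIndividual",
    "BeosaConfig",
    "OptimizeResult",
    "s_transfer",
    "v_transfer",
    "init_population",
    "position_update",
    "binarize",
    "feature_fitness",
    "apply_mask",
    "optimize",
]

UNSET_FITNESS = math.inf


def s_transfer(x):
    """S-shaped (sigmoid) transfer function, S(x) = 1 / (1 + e^-x)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def v_transfer(x):
    """V-shaped transfer function, V(x) = |tanh(x)|."""
    return np.abs(np.tanh(np.asarray(x, dtype=float)))


_TRANSFERS = {"S": s_transfer, "V": v_transfer}


@dataclass
class BinaryIndividual:
    """One candidate solution.

    pos is strictly binary; shadow is the continuous pre-binarization
    position the transfer function acts on.  Lower fitness is better.
    """

    index: int
    pos: np.ndarray
    shadow: np.ndarray
    fitness: float = UNSET_FITNESS

    def __post_init__(self):
        self.pos = np.asarray(self.pos)
        self.shadow = np.asarray(self.shadow, dtype=float)
        if self.pos.shape != self.shadow.shape:
            raise ValueError("pos and shadow must have equal length")
        if not np.isin(self.pos, (0, 1)).all():
            raise ValueError("pos must contain only 0s and 1s")
        self.pos = self.pos.astype(int)

    @property
    def dim(self) -> int:
        return self.pos.size


@dataclass
class BeosaConfig:
    """Optimizer settings.

    srate routes that fraction of updates through the S-shaped
    (exploration) branch, the rest through the V-shaped (intensification)
    branch; lrate sets the floor on how strongly intensified individuals are
    pulled toward the incumbent best.  recruitment_rate and the four contact
    rates (infected, host, dead, recovered contacts) size the per-iteration
    "infected" update set.
    """

    pop_size: int = 20
    max_iter: int = 50
    srate: float = 0.5
    lrate: float = 0.5
    recruitment_rate: float = 0.1
    contact_rates: tuple = (0.1, 0.1, 0.1, 0.1)
    seed: int = 0
    transfer: str = "S"
    printed_rule: bool = True  # bit = 1 iff r > T(x); False flips to r < T(x)

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        rates = (self.srate, self.lrate, self.recruitment_rate, *self.contact_rates)
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.transfer not in _TRANSFERS:
            raise ValueError(f"transfer must be one of {sorted(_TRANSFERS)}")


@dataclass
class OptimizeResult:
    """Best individual found, the best-so-far trace, and evaluation count."""

    best: BinaryIndividual
    history: list = field(default_factory=list)
    evaluations: int = 0


def init_population(pop_size: int, dim: int, seed: int) -> list:
    """Seeded Bernoulli(0.5) population of binary individuals."""
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    return _init_population(rng, pop_size, dim)


def _init_population(rng, pop_size, dim):
    pop = []
    for i in range(pop_size):
        pos = rng.integers(0, 2, size=dim)
        pop.append(BinaryIndividual(index=i, pos=pos, shadow=pos.astype(float)))
    return pop


def position_update(ind: BinaryIndividual, best: BinaryIndividual,
                    delta: float, rand: float) -> np.ndarray:
    """Continuous move Δ·e^rand·cos(2π·rand)·(ind − best).

    The returned vector becomes the individual's new shadow position; the
    caller re-binarizes it.  rand is a draw from uniform[-1, 1].
    """
    if ind.dim != best.dim:
        raise ValueError("ind and best must have equal dim")
    scale = delta * math.exp(rand) * math.cos(2.0 * math.pi * rand)
    shadow = scale * (ind.pos.astype(float) - best.pos.astype(float))
    ind.shadow = shadow
    return shadow


def binarize(shadow: np.ndarray, transfer: str, rng, printed_rule: bool = True) -> np.ndarray:
    """Stochastic binarization through a transfer function.

    For each dimension k a uniform r in [0, 1) is drawn and the bit is set
    to 1 when r > T(shadow_k) (the printed rule; pass printed_rule=False for
    the conventional r < T(shadow_k) direction).
    """
    shadow = np.asarray(shadow, dtype=float)
    if not np.all(np.isfinite(shadow)):
        raise ValueError("shadow contains NaN/inf")
    t = _TRANSFERS[transfer](shadow)
    r = rng.random(shadow.shape)
    bits = (r > t) if printed_rule else (r < t)
    return bits.astype(int)


def apply_mask(features, mask) -> np.ndarray:
    """Keep the columns where mask == 1, preserving order.

    Accepts a plain 2-D array or a FeatureMatrix-like object with .X.
    """
    X = np.asarray(getattr(features, "X", features), dtype=float)
    mask = np.asarray(mask).astype(int)
    if mask.size != X.shape[1]:
        raise ValueError(f"mask length {mask.size} != feature dim {X.shape[1]}")
    return X[:, mask == 1]


def feature_fitness(mask, features, labels, classifier=None, alpha: float = 0.99,
                    n_splits: int = 3, seed: int = 0) -> float:
    """Wrapper fitness alpha·(1 − acc) + (1 − alpha)·|F|/dim.

    acc is the stratified k-fold cross-validated accuracy of the wrapper
    classifier (k-NN by default) on the masked columns; |F| counts selected
    features.  An all-zero mask scores the worst possible value 1.0 so the
    optimizer can escape it rather than crash.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.neighbors import KNeighborsClassifier

    mask = np.asarray(mask).astype(int)
    X = np.asarray(getattr(features, "X", features), dtype=float)
    if mask.size != X.shape[1]:
        raise ValueError(f"mask length {mask.size} != feature dim {X.shape[1]}")
    n_sel = int(mask.sum())
    if n_sel == 0:
        return alpha + (1.0 - alpha)  # = 1.0, worst case by construction
    if classifier is None:
        classifier = KNeighborsClassifier(n_neighbors=5)
    y = np.asarray(labels)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    acc = cross_val_score(classifier, X[:, mask == 1], y, cv=cv, scoring="accuracy").mean()
    return alpha * (1.0 - acc) + (1.0 - alpha) * n_sel / mask.size


def _infected_set(rng, pop_size, config):
    """Per-iteration update set: a recruited core plus contact-rate draws."""
    n_recruit = max(1, math.ceil(config.recruitment_rate * pop_size))
    infected = set(rng.choice(pop_size, size=n_recruit, replace=False).tolist())
    for i in range(pop_size):
        for p in config.contact_rates:
            if rng.random() < p:
                infected.add(i)
                break
    return sorted(infected)


def optimize(dim: int, fitness_fn, config: BeosaConfig) -> OptimizeResult:
    """Run BEOSA on a binary objective of the given dimension.

    Each iteration an infected subset of the population is perturbed: with
    probability srate through the exploration branch (continuous move via
    position_update, then transfer-function binarization), otherwise through
    the intensification branch, which pulls the individual's bits toward the
    incumbent best with per-bit probability lrate + (1 − lrate)·V(shadow)
    and mutates at rate 1/dim.  The best-so-far individual is tracked
    separately, so the reported history is non-increasing.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(config.seed)
    pop = _init_population(rng, config.pop_size, dim)

    evaluations = 0
    for ind in pop:
        ind.fitness = float(fitness_fn(ind.pos))
        evaluations += 1
    best = min(pop, key=lambda i: i.fitness)
    best = replace(best, pos=best.pos.copy(), shadow=best.shadow.copy())

    history = []
    for t in range(config.max_iter):
        delta = 1.0 - t / config.max_iter  # linearly decaying change factor
        for i in _infected_set(rng, config.pop_size, config):
            ind = pop[i]
            rand = rng.uniform(-1.0, 1.0)
            shadow = position_update(ind, best, delta, rand)
            if rng.random() < config.srate:
                new_pos = binarize(shadow, config.transfer, rng,
                                   printed_rule=config.printed_rule)
            else:
                adopt = config.lrate + (1.0 - config.lrate) * v_transfer(shadow)
                take_best = rng.random(dim) < adopt
                new_pos = np.where(take_best, best.pos, ind.pos)
                flip = rng.random(dim) < 1.0 / dim
                new_pos = np.where(flip, 1 - new_pos, new_pos)
            ind.pos = new_pos.astype(int)
            try:
                ind.fitness = float(fitness_fn(ind.pos))
            except Exception as exc:
                raise RuntimeError(
                    f"fitness_fn failed at iteration {t}, individual {i}"
                ) from exc
            evaluations += 1
            if ind.fitness < best.fitness:
                best = replace(ind, pos=ind.pos.copy(), shadow=ind.shadow.copy())
        history.append(best.fitness)

    return OptimizeResult(best=best, history=history, evaluations=evaluations)
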