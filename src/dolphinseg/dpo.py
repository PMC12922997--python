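"""Dolphin partner optimization: a population metaheuristic for
hyperparameter search.

Each candidate ("dolphin") lives in the normalized unit box.  Every
generation each dolphin forms a team of its k nearest neighbours, picks
the best-fitness partner, and either exploits (moves a random fraction of
the way toward the partner) or explores (takes a uniform random step
whose radius shrinks linearly to zero over the run).  The exploit
probability follows the convergence schedule

    P(l) = P1 + (1 - P1) * (l - 1) / (L - 1),      l = 1..L,

so the search narrows as the swarm closes in.  Elitism (on by default)
keeps the best-ever candidate, making the best-so-far trace monotone.
`tune_hyperparameters` applies the optimizer to the segmenter's
(learning rate, hidden units, dropout, batch size) space with a Dice-based
fitness that also charges a small model-size penalty.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .features import FeatureConfig
from .model import Hyperparameters, train as train_model
from .samples import ImageSample


@dataclasses.dataclass
class Dolphin:
    """One candidate: a normalized position and (optionally) its fitness."""

    position: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if np.any(self.position < 0.0) or np.any(self.position > 1.0):
            raise ValueError("dolphin position must lie in the unit box")


@dataclasses.dataclass
class DPOConfig:
    """Population/schedule settings.

    pop_size : number of dolphins N (>= 2)
    generations : schedule length L (>= 2; the convergence factor divides by L-1)
    p1 : exploitation probability at generation 1
    alpha : exploitation step scale (fraction of the gap to the partner)
    beta : exploration step scale (initial half-width of the random step)
    team_size : nearest-neighbour team size k (< N)
    seed : master seed; the whole run is a pure function of it
    elitism : keep the best-ever candidate (monotone best-so-far trace)
    """

    pop_size: int = 10
    generations: int = 20
    p1: float = 0.3
    alpha: float = 0.8
    beta: float = 0.4
    team_size: int = 3
    seed: int = 0
    elitism: bool = True

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.generations < 2:
            raise ValueError("generations must be >= 2 (schedule divides by L-1)")
        if not 0.0 <= self.p1 <= 1.0:
            raise ValueError("p1 must lie in [0, 1]")
        if self.team_size >= self.pop_size:
            raise ValueError("team_size must be < pop_size")


@dataclasses.dataclass(frozen=True)
class SearchDimension:
    """One search-space axis: continuous, log_continuous or integer."""

    name: str
    kind: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "log_continuous", "integer"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if not self.low < self.high:
            raise ValueError(f"dimension {self.name}: low must be < high")
        if self.kind == "log_continuous" and self.low <= 0:
            raise ValueError(f"dimension {self.name}: log scale needs low > 0")

    def decode(self, p: float) -> float | int:
        p = min(max(p, 0.0), 1.0)
        if self.kind == "continuous":
            return self.low + p * (self.high - self.low)
        if self.kind == "log_continuous":
            return math.exp(math.log(self.low) + p * (math.log(self.high) - math.log(self.low)))
        value = round(self.low + p * (self.high - self.low))
        return int(min(max(value, self.low), self.high))


@dataclasses.dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[SearchDimension, ...]

    @property
    def d(self) -> int:
        return len(self.dimensions)

    def decode(self, position: np.ndarray) -> dict:
        return {dim.name: dim.decode(p) for dim, p in zip(self.dimensions, position)}


def default_search_space(max_units: int = 64) -> SearchSpace:
    """The segmenter's tuning space at desk scale.

    Full-scale bounds are learning rate 1e-4..1e-2 (log), units 32..256,
    dropout 0.1..0.5, batch 8..64; the unit range is narrowed for small
    problems via ``max_units``.
    """
    return SearchSpace((
        SearchDimension("learning_rate", "log_continuous", 1e-4, 1e-2),
        SearchDimension("hidden_units", "integer", 4 if max_units <= 64 else 32, max_units),
        SearchDimension("dropout_rate", "continuous", 0.1, 0.5),
        SearchDimension("batch_size", "integer", 8, 64),
    ))


def convergence_probability(li: int, lN: int, p1: float) -> float:
    """Exploit probability at generation li of lN: P1 + (1-P1)(li-1)/(lN-1)."""
    if lN < 2:
        raise ValueError("lN must be >= 2 (schedule divides by lN - 1)")
    if not 1 <= li <= lN:
        raise ValueError(f"li must lie in [1, {lN}], got {li}")
    return p1 + (1.0 - p1) * (li - 1) / (lN - 1)


def init_population(config: DPOConfig, space: SearchSpace,
                    rng: np.random.Generator) -> list[Dolphin]:
    """N i.i.d. uniform positions in the unit box, fitness unset."""
    return [Dolphin(rng.uniform(0.0, 1.0, size=space.d))
            for _ in range(config.pop_size)]


def form_team(population: list[Dolphin], i: int, k: int) -> list[int]:
    """Indices of the k nearest other dolphins (Euclidean; ties -> lower index)."""
    if k >= len(population):
        raise ValueError(f"team size {k} must be < population size {len(population)}")
    me = population[i].position
    others = [(float(np.linalg.norm(d.position - me)), j)
              for j, d in enumerate(population) if j != i]
    others.sort()  # distance, then index
    return [j for _, j in others[:k]]


def select_partner(team: list[int], population: list[Dolphin]) -> int:
    """Team member with minimal fitness; ties go to the lower index."""
    if not team:
        raise ValueError("team must be non-empty")
    best = min(team, key=lambda j: (population[j].fitness, j))
    return best


def update_position(dolphin: Dolphin, partner: Dolphin, config: DPOConfig,
                    li: int, rng: np.random.Generator,
                    exploit_r: np.ndarray | None = None) -> np.ndarray:
    """One movement step, clipped to the unit box.

    With probability P(li) the dolphin exploits: it moves a random
    per-dimension fraction (``alpha * U(0,1)``) of the way toward its
    partner.  Otherwise it explores: a uniform step of half-width
    ``beta * (1 - (li-1)/(lN-1))``, so the exploration radius shrinks to
    zero by the final generation.  ``exploit_r`` is a test hook that
    forces the exploitation fractions.
    """
    d = dolphin.position.size
    p_exploit = convergence_probability(li, config.generations, config.p1)
    if rng.random() < p_exploit:
        r = rng.uniform(0.0, 1.0, size=d) if exploit_r is None else np.asarray(exploit_r)
        new = dolphin.position + config.alpha * r * (partner.position - dolphin.position)
    else:
        radius = config.beta * (1.0 - (li - 1) / (config.generations - 1))
        new = dolphin.position + radius * rng.uniform(-1.0, 1.0, size=d)
    return np.clip(new, 0.0, 1.0)


def optimize(fitness_fn, space: SearchSpace, config: DPOConfig):
    """Run the full swarm search.

    ``fitness_fn`` maps a decoded parameter dict to a scalar (lower is
    better).  Returns (best decoded parameters, best fitness, trace),
    where trace is a list of per-generation records with the best-so-far
    and generation-mean fitness and every evaluated candidate.
    """
    rng = np.random.default_rng(config.seed)
    population = init_population(config, space, rng)
    return _optimize_loop(fitness_fn, space, config, rng, population)


def _evaluate(dolphin: Dolphin, fitness_fn, space: SearchSpace, cache: dict) -> None:
    decoded = space.decode(dolphin.position)
    key = tuple(sorted(decoded.items()))
    if key not in cache:
        try:
            cache[key] = float(fitness_fn(decoded))
        except Exception as exc:  # surface the offending candidate
            raise RuntimeError(f"fitness function failed for {decoded}") from exc
    dolphin.fitness = cache[key]


def _optimize_loop(fitness_fn, space, config, rng, population):
    cache: dict = {}
    best_pos: np.ndarray | None = None
    best_fit = math.inf
    trace = []
    for li in range(1, config.generations + 1):
        for dolphin in population:
            _evaluate(dolphin, fitness_fn, space, cache)
        fits = np.array([d.fitness for d in population])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_pos = population[gen_best].position.copy()
        trace.append({
            "generation": li,
            "p_exploit": convergence_probability(li, config.generations, config.p1),
            "best_fitness": best_fit if config.elitism else float(fits[gen_best]),
            "gen_best_fitness": float(fits[gen_best]),
            "mean_fitness": float(fits.mean()),
            "candidates": [
                {"decoded": space.decode(d.position), "fitness": float(d.fitness)}
                for d in population
            ],
        })
        if li == config.generations:
            break
        new_positions = []
        for i, dolphin in enumerate(population):
            team = form_team(population, i, config.team_size)
            partner = population[select_partner(team, population)]
            new_positions.append(update_position(dolphin, partner, config, li, rng))
        for dolphin, pos in zip(population, new_positions):
            dolphin.position = pos
            dolphin.fitness = None
        if config.elitism and best_pos is not None:
            population[0].position = best_pos.copy()
    if not config.elitism:
        # report the best of the final evaluation sweep
        best_fit = float(min(d.fitness for d in population))
        best_pos = min(population, key=lambda d: (d.fitness,)).position.copy()
    return space.decode(best_pos), best_fit, trace


# ---------------------------------------------------------------------------
# hyperparameter tuning for the segmenter


def hyperparameter_fitness(val_dsc_pct: float, hidden_units: int,
                           max_units: int, size_penalty: float = 0.05) -> float:
    """(1 - valDSC/100) + penalty * hidden_units / max_units — lower is better."""
    return (1.0 - val_dsc_pct / 100.0) + size_penalty * hidden_units / max_units


def tune_hyperparameters(train_set: list[ImageSample], val_set: list[ImageSample],
                         space: SearchSpace | None = None,
                         config: DPOConfig | None = None,
                         feature_config: FeatureConfig | None = None,
                         epochs: int = 30, size_penalty: float = 0.05,
                         upsample: str = "bilinear",
                         baseline: Hyperparameters | None = None):
    """Tune (learning rate, hidden units, dropout, batch size) by swarm search.

    Each candidate trains a segmenter for a reduced ``epochs`` budget
    (seeded from the optimizer's seed) and is scored by validation Dice
    plus a model-size penalty.  The documented default `Hyperparameters`
    (or ``baseline``) seeds dolphin 0, so with elitism the tuned fitness
    can never exceed the default's.  Returns (best Hyperparameters,
    report dict).
    """
    space = space or default_search_space()
    config = config or DPOConfig(pop_size=6, generations=5)
    feature_config = feature_config or FeatureConfig()
    baseline = baseline or Hyperparameters()
    max_units = next(d.high for d in space.dimensions if d.name == "hidden_units")

    def fitness(decoded: dict) -> float:
        hp = Hyperparameters(
            learning_rate=decoded["learning_rate"],
            hidden_units=int(decoded["hidden_units"]),
            dropout_rate=decoded["dropout_rate"],
            batch_size=int(decoded["batch_size"]),
            epochs=epochs,
        )
        _, history = train_model(hp, train_set, val_set, config.seed,
                                 feature_config, upsample)
        best_epoch = history["best_epoch"]
        val_dsc = history["val_dsc"][best_epoch]
        return hyperparameter_fitness(val_dsc, hp.hidden_units, max_units, size_penalty)

    rng = np.random.default_rng(config.seed)
    population = init_population(config, space, rng)
    population[0] = Dolphin(_encode(baseline, space))
    best_decoded, best_fit, trace = _optimize_loop(fitness, space, config, rng, population)
    best_hp = Hyperparameters(
        learning_rate=best_decoded["learning_rate"],
        hidden_units=int(best_decoded["hidden_units"]),
        dropout_rate=best_decoded["dropout_rate"],
        batch_size=int(best_decoded["batch_size"]),
        epochs=epochs,
    )
    baseline_fitness = fitness({
        "learning_rate": baseline.learning_rate,
        "hidden_units": baseline.hidden_units,
        "dropout_rate": baseline.dropout_rate,
        "batch_size": baseline.batch_size,
    })
    report = {
        "best": best_decoded,
        "best_fitness": best_fit,
        "baseline": baseline.as_dict(),
        "baseline_fitness": baseline_fitness,
        "trace": trace,
        "config": dataclasses.asdict(config),
        "epochs_per_evaluation": epochs,
        "size_penalty": size_penalty,
    }
    return best_hp, report


def _encode(hp: Hyperparameters, space: SearchSpace) -> np.ndarray:
    """Inverse of SearchSpace.decode for warm-starting a known candidate."""
    values = {"learning_rate": hp.learning_rate, "hidden_units": hp.hidden_units,
              "dropout_rate": hp.dropout_rate, "batch_size": hp.batch_size}
    pos = []
    for dim in space.dimensions:
        v = float(values[dim.name])
        v = min(max(v, dim.low), dim.high)
        if dim.kind == "log_continuous":
            p = (math.log(v) - math.log(dim.low)) / (math.log(dim.high) - math.log(dim.low))
        else:
            p = (v - dim.low) / (dim.high - dim.low)
        pos.append(min(max(p, 0.0), 1.0))
    return np.array(pos)
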