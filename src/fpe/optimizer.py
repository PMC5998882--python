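"""Discrete flower pollination search for a size-Q candidate essential set.

A pollen encodes a candidate solution as a set of exactly Q distinct
protein IDs; its fitness is the additive GSC of the set.  The search
alternates, per pollen and iteration, between

* **global pollination** — keep the members shared with a random fraction of
  the best set found so far (Gbest) and refill the remaining slots by a
  uniform draw over the whole network, and
* **local pollination** — the identity move (the position is kept as is),

chosen by the switch probability p (a uniform draw below p triggers the
global move).  Updates are accepted greedily: a pollen is replaced only if
the proposal's fitness is at least its own, so the best-so-far fitness is
non-decreasing.  The population is seeded from the Q highest-degree
proteins, each non-elite pollen perturbed by swapping a fixed fraction of
members for random outsiders.

All randomness flows through a single ``numpy.random.Generator`` consumed in
a documented order (initialization first, then per-iteration, per-pollen
draws), so a run is a pure function of its inputs and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data_io import ProteinNetwork
from .fitness import GSCConfig, gsc_values, rank_descending
from .scoring import ProteinScoreTable

__all__ = [
    "Pollen",
    "FPEConfig",
    "OptimizerState",
    "FPEResult",
    "initialize_population",
    "global_pollination",
    "local_pollination",
    "step",
    "run_fpe",
]


@dataclass(frozen=True)
class Pollen:
    """A candidate set of exactly Q distinct proteins with its GSC fitness."""

    members: frozenset[str]
    fitness: float

    @classmethod
    def from_members(cls, members: Sequence[str] | frozenset[str],
                     gsc: Mapping[str, float]) -> "Pollen":
        ms = frozenset(members)
        return cls(members=ms, fitness=sum(gsc[p] for p in ms))


@dataclass
class FPEConfig:
    """Search parameters.

    q               candidate-set size (the paper-scale default is 600)
    p               switch probability; a uniform draw < p triggers the
                    global move (0.3 is the recommended value)
    alpha           GSC mixing weight, see :class:`fpe.fitness.GSCConfig`
    population_size number of pollens N
    iterations      fixed iteration budget T_max (no early stopping)
    beta            perturbance factor: fraction of the elite set swapped out
                    when seeding each non-elite pollen
    gbest_fraction  γ: fraction of Gbest sampled in the global move's
                    intersection step
    seed            RNG seed; None draws fresh entropy
    """

    q: int = 600
    p: float = 0.3
    alpha: float = 0.6
    population_size: int = 20
    iterations: int = 100
    beta: float = 0.2
    gbest_fraction: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("q must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("switch probability p must lie in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if not 0.0 < self.gbest_fraction <= 1.0:
            raise ValueError("gbest_fraction must lie in (0, 1]")
        if self.population_size < 1:
            raise ValueError("population_size must be at least 1")
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")

    def gsc_config(self) -> GSCConfig:
        return GSCConfig(alpha=self.alpha)


@dataclass
class OptimizerState:
    """Population, best-so-far pollen, and the per-iteration Gbest history."""

    population: list[Pollen]
    gbest: Pollen
    history: list[float] = field(default_factory=list)


@dataclass
class FPEResult:
    """Final ranking of the Gbest members plus the full optimizer state."""

    ranking: list[str]
    gsc: dict[str, float]
    state: OptimizerState

    @property
    def gbest_fitness(self) -> float:
        return self.state.gbest.fitness


def _sorted_members(members: frozenset[str]) -> list[str]:
    return sorted(members)


def initialize_population(
    network: ProteinNetwork,
    gsc: Mapping[str, float],
    config: FPEConfig,
    rng: np.random.Generator,
) -> OptimizerState:
    """Seed the population from the top-Q-degree proteins.

    Pollen 0 is exactly the Q highest-degree nodes (degree ties broken by
    ID); every other pollen is that elite set with ⌈β·Q⌉ uniformly chosen
    members replaced by uniformly chosen non-members, preserving
    distinctness.
    """
    nodes = network.sorted_nodes()
    if config.q > len(nodes):
        raise ValueError(
            f"q={config.q} exceeds the network's {len(nodes)} nodes"
        )
    by_degree = sorted(nodes, key=lambda p: (-network.degree(p), p))
    elite_list = by_degree[: config.q]
    elite = Pollen.from_members(elite_list, gsc)
    outside = sorted(set(nodes) - elite.members)

    population = [elite]
    n_swap = min(math.ceil(config.beta * config.q), config.q, len(outside))
    for _ in range(config.population_size - 1):
        members = list(elite_list)
        if n_swap > 0:
            drop_idx = rng.choice(config.q, size=n_swap, replace=False)
            add_idx = rng.choice(len(outside), size=n_swap, replace=False)
            keep = [m for k, m in enumerate(members) if k not in set(drop_idx.tolist())]
            members = keep + [outside[k] for k in add_idx]
        population.append(Pollen.from_members(members, gsc))

    gbest = max(population, key=lambda pl: pl.fitness)
    return OptimizerState(population=population, gbest=gbest, history=[gbest.fitness])


def global_pollination(
    pollen: Pollen,
    gbest: Pollen,
    network: ProteinNetwork,
    gsc: Mapping[str, float],
    config: FPEConfig,
    rng: np.random.Generator,
) -> Pollen:
    """Gbest-guided move: intersect with a sampled slice of Gbest, refill at random.

    1. draw a uniform subset G′ of Gbest of size ⌈γ·Q⌉;
    2. keep K = pollen ∩ G′;
    3. fill the remaining Q − |K| slots without replacement from V ∖ K;
    4. the new position is K plus the fill, with fitness recomputed.
    """
    q = config.q
    gbest_list = _sorted_members(gbest.members)
    n_slice = min(math.ceil(config.gbest_fraction * q), len(gbest_list))
    slice_idx = rng.choice(len(gbest_list), size=n_slice, replace=False)
    g_slice = {gbest_list[k] for k in slice_idx}
    kept = pollen.members & g_slice

    pool = sorted(network.nodes - kept)
    n_fill = q - len(kept)
    fill_idx = rng.choice(len(pool), size=n_fill, replace=False)
    members = frozenset(kept) | {pool[k] for k in fill_idx}
    return Pollen.from_members(members, gsc)


def local_pollination(pollen: Pollen) -> Pollen:
    """The local move keeps the position unchanged (identity)."""
    return pollen


def step(
    state: OptimizerState,
    network: ProteinNetwork,
    gsc: Mapping[str, float],
    config: FPEConfig,
    rng: np.random.Generator,
) -> OptimizerState:
    """One iteration: per pollen, switch between the two moves and accept greedily.

    For each pollen independently a uniform u is drawn; u < p triggers
    global pollination, otherwise the local identity move.  The proposal
    replaces the pollen only when its fitness is at least the incumbent's.
    Gbest is updated only on a strict fitness improvement (ties keep the
    incumbent Gbest).
    """
    new_population: list[Pollen] = []
    gbest = state.gbest
    for pollen in state.population:
        if rng.random() < config.p:
            proposal = global_pollination(pollen, gbest, network, gsc, config, rng)
        else:
            proposal = local_pollination(pollen)
        accepted = proposal if proposal.fitness >= pollen.fitness else pollen
        new_population.append(accepted)
        if accepted.fitness > gbest.fitness:
            gbest = accepted
    history = state.history + [gbest.fitness]
    return OptimizerState(population=new_population, gbest=gbest, history=history)


def run_fpe(
    network: ProteinNetwork,
    scores: ProteinScoreTable | Mapping[str, float],
    config: FPEConfig | None = None,
) -> FPEResult:
    """Full search: initialize, iterate T_max steps, rank the Gbest members.

    ``scores`` may be a full PeC/SL/PC table (reduced with the configured α)
    or an already-computed per-protein GSC map.  Identical inputs and seed
    give a byte-identical ranking.
    """
    if config is None:
        config = FPEConfig()
    if isinstance(scores, ProteinScoreTable):
        gsc_all = gsc_values(scores, config.gsc_config())
    else:
        gsc_all = dict(scores)
    # candidates are network nodes only; scored-but-absent proteins cannot enter
    gsc = {p: gsc_all.get(p, 0.0) for p in network.nodes}

    rng = np.random.default_rng(config.seed)
    state = initialize_population(network, gsc, config, rng)
    for _ in range(config.iterations):
        state = step(state, network, gsc, config, rng)
    ranking = rank_descending(state.gbest.members, gsc)
    return FPEResult(ranking=ranking, gsc={p: gsc[p] for p in ranking}, state=state)
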