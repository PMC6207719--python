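"""Elementary rules of the spatial Ultimatum Game.

The model puts one agent on each site of a periodic square lattice.  An
agent carries an unchanging strategy ``(p, q)`` — the fraction ``p`` it
offers when proposing, and the minimum offer ``q`` it accepts when
responding — together with the wealth it has accumulated from games won.

Three elementary operations make up the dynamics:

* :func:`play_game` — the one-shot Ultimatum Game pay-off rule;
* :func:`select_victim` — the wealth-biased choice of which neighbour a
  reproducing agent replaces;
* :func:`mutate` — the bounded uniform perturbation applied to an
  inherited strategy.

Everything here is pure and operates on scalars; the compiled event loop
in :mod:`ugevolve.scheduler` re-implements the same rules on flat arrays
for speed, and the test-suite cross-checks the two paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Strategy",
    "AgentState",
    "ModelParams",
    "play_game",
    "select_victim",
    "mutate",
    "MUTATION_HALF_WIDTH_FACTOR",
]

#: A zero-mean uniform law with standard deviation mu has half-width sqrt(3)*mu.
MUTATION_HALF_WIDTH_FACTOR = math.sqrt(3.0)


class Strategy(NamedTuple):
    """An Ultimatum Game strategy: offer ``p`` and acceptance threshold ``q``.

    Both coordinates are dimensionless fractions in the closed unit
    interval.  Strategies live in the unit square; the region
    ``0 <= q <= p <= 1`` (offers acceptable to one's own kin) is the
    *dominant triangle* into which evolving populations self-organise.
    """

    p: float
    q: float

    def validate(self) -> "Strategy":
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValueError(f"strategy {self} outside the unit square")
        return self

    @property
    def in_dominant_triangle(self) -> bool:
        return self.q <= self.p


@dataclass
class AgentState:
    """One lattice occupant: strategy, accumulated wealth, and birth time.

    Wealth starts at exactly zero (newborns inherit nothing) and is
    non-decreasing over an agent's lifetime: the game only ever credits
    pay-offs, it never debits the proposer — each accepted game splits one
    unit of exogenous resource between the pair.
    """

    strategy: Strategy
    wealth: float = 0.0
    birth_time: float = 0.0

    def __post_init__(self) -> None:
        self.strategy = Strategy(*self.strategy).validate()
        if self.wealth < 0.0:
            raise ValueError("wealth must be non-negative")

    def age(self, clock: float) -> float:
        return clock - self.birth_time


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the lattice model.

    Parameters
    ----------
    R
        Death (= birth) rate per agent per unit time.  Games are played at
        unit rate per agent, so ``R >> 1`` makes pay-offs rare events on
        the scale of a lifetime.
    mu
        Mutation scale: the standard deviation of the uniform perturbation
        applied independently to each inherited strategy coordinate.
    L
        Lattice side length; the population is exactly ``L**2`` at all
        times.
    seed
        Seed for the single random stream driving a run.
    mutation_boundary
        How the ``[0, 1]`` constraint on offspring coordinates is
        enforced: ``"resample"`` (redraw the perturbation until the
        coordinate is admissible; default) or ``"clip"`` (project onto
        the interval, creating boundary atoms).
    """

    R: float
    mu: float
    L: int
    seed: int = 0
    mutation_boundary: str = "resample"

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError("R must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.L < 2:
            raise ValueError("L must be at least 2")
        if self.mutation_boundary not in ("resample", "clip"):
            raise ValueError("mutation_boundary must be 'resample' or 'clip'")

    @property
    def n_agents(self) -> int:
        return self.L * self.L


def play_game(proposer: Strategy, responder: Strategy) -> tuple[float, float]:
    """One-shot Ultimatum Game between a proposer and a responder.

    The proposer offers the fraction ``p`` of a unit resource.  The
    responder accepts iff ``p >= q`` (the comparison is inclusive:
    equality accepts).  On acceptance the proposer keeps ``1 - p`` and the
    responder receives ``p``; on rejection neither receives anything.

    Returns
    -------
    (proposer_payoff, responder_payoff)
        Summing to 1 on acceptance and to 0 on rejection.
    """
    p = proposer[0]
    if p >= responder[1]:
        return 1.0 - p, p
    return 0.0, 0.0


def select_victim(
    neighbor_wealths: Sequence[float], rng: np.random.Generator
) -> int:
    """Choose which of four neighbours a reproducing agent replaces.

    With probability 1/2 the poorest neighbour is chosen (ties between
    equal-poorest broken uniformly at random); with probability 1/2 a
    neighbour is chosen uniformly at random regardless of wealth.  Ties
    are exact numerical equality — in this model ties essentially only
    occur at ``w = 0``, among agents that have never won a game.

    Parameters
    ----------
    neighbor_wealths
        Exactly four non-negative wealths, indexed 0..3.
    rng
        Source of randomness.

    Returns
    -------
    int
        Index in ``{0, 1, 2, 3}`` of the neighbour to be replaced.
    """
    w = np.asarray(neighbor_wealths, dtype=float)
    if w.shape != (4,):
        raise ValueError("exactly four neighbour wealths required")
    if rng.random() < 0.5:
        poorest = np.flatnonzero(w == w.min())
        return int(poorest[rng.integers(len(poorest))])
    return int(rng.integers(4))


def _draw_bounded(x: float, half_width: float, rng: np.random.Generator,
                  boundary: str) -> float:
    if half_width <= 0.0:
        return x
    if boundary == "resample":
        while True:
            cand = x + rng.uniform(-half_width, half_width)
            if 0.0 <= cand <= 1.0:
                return cand
    cand = x + rng.uniform(-half_width, half_width)
    return min(1.0, max(0.0, cand))


def mutate(
    parent: Strategy,
    mu: float,
    rng: np.random.Generator,
    boundary: str = "resample",
) -> Strategy:
    """Produce an offspring strategy by bounded uniform mutation.

    Each coordinate of the parent strategy is perturbed independently by
    a draw from the zero-mean uniform distribution with standard
    deviation ``mu`` (half-width ``sqrt(3)*mu``), subject to the offspring
    coordinate remaining in ``[0, 1]``.

    The constraint is enforced per coordinate either by rejection
    resampling (``boundary="resample"``, default — preserves the uniform
    shape on the admissible set) or by clipping (``boundary="clip"`` —
    creates atoms at 0 and 1).  Near a boundary, resampling biases the
    perturbation away from it; this is unavoidable for any bounded law.

    The offer coordinate is drawn first, then the threshold; the compiled
    event loop follows the same order.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if boundary not in ("resample", "clip"):
        raise ValueError("boundary must be 'resample' or 'clip'")
    hw = MUTATION_HALF_WIDTH_FACTOR * mu
    return Strategy(
        _draw_bounded(parent[0], hw, rng, boundary),
        _draw_bounded(parent[1], hw, rng, boundary),
    )
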