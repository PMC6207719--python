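"""Initial lattice configurations.

Two protocols are used for production runs — a fully randomized start
(no preconceptions about the final state) and a half-and-half start that
pits an archetypally selfish phase against an archetypally generous one
across a straight interface — plus monomorphic states for testing.

Founders are treated like newborns: wealth exactly zero and birth time
zero, so the early-time mean age grows like the clock itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model_core import ModelParams, Strategy
from .scheduler import LatticeState

__all__ = [
    "InitSpec",
    "init_random",
    "init_half_and_half",
    "init_monomorphic",
    "build_lattice",
]

_MODES = ("random_uniform", "half_and_half", "monomorphic")


@dataclass(frozen=True)
class InitSpec:
    """Named initialization protocol.

    ``mode`` is one of ``random_uniform``, ``half_and_half`` or
    ``monomorphic``; the latter requires ``monomorphic_strategy``.
    """

    mode: str
    monomorphic_strategy: Optional[Strategy] = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode == "monomorphic" and self.monomorphic_strategy is None:
            raise ValueError("monomorphic mode requires monomorphic_strategy")


def _empty_state(params: ModelParams, rng: np.random.Generator) -> dict:
    L = params.L
    return dict(
        params=params,
        w=np.zeros((L, L)),
        birth_time=np.zeros((L, L)),
        clock=0.0,
        rng=rng,
    )


def _rng_for(params: ModelParams, rng) -> np.random.Generator:
    # Initial strategies use a numpy Generator stream derived from the
    # model seed; the event loop draws from its own stream seeded with
    # the same integer.  Both are fixed by params.seed.
    if rng is not None:
        return rng
    return np.random.default_rng(params.seed)


def init_random(params: ModelParams, rng=None) -> LatticeState:
    """Every site gets independent ``p, q ~ uniform[0, 1]``.

    The population initially covers the whole unit square, so about half
    of all agents start with the self-defeating property ``p < q``.
    """
    rng = _rng_for(params, rng)
    L = params.L
    return LatticeState(
        p=rng.random((L, L)),
        q=rng.random((L, L)),
        **_empty_state(params, rng),
    )


def init_half_and_half(params: ModelParams, rng=None) -> LatticeState:
    """Selfish half against generous half across a straight interface.

    Columns ``x < L/2`` hold the archetypal selfish strategy
    ``(p, q) = (0, 0)``; columns ``x >= L/2`` are maximally generous,
    ``p = 1`` with ``q`` drawn uniformly from ``[0, 1]``.  Two vertical
    interfaces exist: one down the middle and one at the ``x = 0``
    periodic boundary.  All agents on both sides start inside the closed
    dominant triangle (``p >= q``).

    Requires even ``L`` so the halves are equal.
    """
    if params.L % 2:
        raise ValueError("half_and_half initialization requires even L")
    rng = _rng_for(params, rng)
    L = params.L
    p = np.zeros((L, L))
    q = np.zeros((L, L))
    p[:, L // 2:] = 1.0
    q[:, L // 2:] = rng.random((L, L // 2))
    return LatticeState(p=p, q=q, **_empty_state(params, rng))


def init_monomorphic(
    params: ModelParams, strategy: Strategy, rng=None
) -> LatticeState:
    """Every site holds the same strategy (used for controlled tests)."""
    s = Strategy(*strategy).validate()
    rng = _rng_for(params, rng)
    L = params.L
    return LatticeState(
        p=np.full((L, L), s.p),
        q=np.full((L, L), s.q),
        **_empty_state(params, rng),
    )


def build_lattice(spec: InitSpec, params: ModelParams, rng=None) -> LatticeState:
    """Construct the initial state named by ``spec``."""
    if spec.mode == "random_uniform":
        return init_random(params, rng)
    if spec.mode == "half_and_half":
        return init_half_and_half(params, rng)
    return init_monomorphic(params, spec.monomorphic_strategy, rng)
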