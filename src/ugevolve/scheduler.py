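"""Continuous-time stochastic dynamics on the lattice.

Agents sit on an ``L x L`` torus with von Neumann (4-neighbour)
connectivity.  Two event types drive the dynamics:

* **gaming**, at unit rate per agent — the selected agent proposes its
  offer to one of its four nearest neighbours, chosen uniformly;
* **reproduction**, at rate ``R`` per agent — the selected agent places a
  mutated offspring of wealth zero onto a neighbouring site chosen by the
  wealth-biased victim rule, killing the occupant.

Events are applied strictly sequentially (asynchronous updating).  The
clock advances by exponential waiting times of mean ``1/(L**2 * (1+R))``
(exact Gillespie scheme); a fixed-increment mode with the same mean step
is available for comparison.

:func:`run` drives the compiled event loop and records the full
observable set at the requested sample times.  :func:`step` applies one
elementary event in pure Python; it exists as a slow, transparent
reference path for the unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .model_core import (
    MUTATION_HALF_WIDTH_FACTOR,
    ModelParams,
    Strategy,
    mutate,
    play_game,
    select_victim,
)

__all__ = ["LatticeState", "step", "run", "neighbor_table"]

#: Number of bins used for the offer-resolved reproduction tally.
DEFAULT_P_BINS = 20


def neighbor_table(L: int) -> np.ndarray:
    """Flat-index von Neumann neighbour table on the ``L x L`` torus.

    Site ``(x, y)`` (x the column) has flat index ``y*L + x``; neighbours
    are listed in the order +x, -x, +y, -y.
    """
    idx = np.arange(L * L)
    x = idx % L
    y = idx // L
    return np.stack(
        [
            y * L + (x + 1) % L,
            y * L + (x - 1) % L,
            ((y + 1) % L) * L + x,
            ((y - 1) % L) * L + x,
        ],
        axis=1,
    ).astype(np.int64)


@dataclass
class LatticeState:
    """Full state of a lattice population.

    The strategy and bookkeeping fields are stored as ``(L, L)`` float
    arrays indexed ``[y, x]``; the population is exactly ``L**2`` at all
    times because every reproduction replaces exactly one neighbour.
    ``event_counts`` tallies ``[games, games_accepted, reproductions]``.
    """

    params: ModelParams
    p: np.ndarray
    q: np.ndarray
    w: np.ndarray
    birth_time: np.ndarray
    clock: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    event_counts: np.ndarray = field(
        default_factory=lambda: np.zeros(3, dtype=np.int64)
    )

    def __post_init__(self) -> None:
        L = self.params.L
        for name in ("p", "q", "w", "birth_time"):
            a = np.ascontiguousarray(getattr(self, name), dtype=np.float64)
            if a.shape != (L, L):
                raise ValueError(f"{name} must have shape ({L}, {L})")
            setattr(self, name, a)
        self.validate()

    def validate(self) -> None:
        if np.any((self.p < 0) | (self.p > 1) | (self.q < 0) | (self.q > 1)):
            raise ValueError("strategies must lie in the unit square")
        if np.any(self.w < 0):
            raise ValueError("wealth must be non-negative")

    @property
    def n_agents(self) -> int:
        return self.params.n_agents

    def ages(self) -> np.ndarray:
        return self.clock - self.birth_time

    def copy(self) -> "LatticeState":
        return LatticeState(
            params=self.params,
            p=self.p.copy(),
            q=self.q.copy(),
            w=self.w.copy(),
            birth_time=self.birth_time.copy(),
            clock=self.clock,
            rng=self.rng,
            event_counts=self.event_counts.copy(),
        )


def step(state: LatticeState, *, time_advance: str = "exponential") -> LatticeState:
    """Apply one elementary event in place (pure-Python reference path).

    With probability ``1/(1+R)`` the event is a game, otherwise a
    reproduction; the clock advances by an exponential waiting time of
    mean ``1/(L**2 * (1+R))`` (or that fixed increment when
    ``time_advance="fixed"``).  Returns the mutated state for chaining.
    """
    params = state.params
    L = params.L
    n = params.n_agents
    rng = state.rng
    rate = n * (1.0 + params.R)
    if time_advance == "exponential":
        state.clock += rng.exponential(1.0 / rate)
    elif time_advance == "fixed":
        state.clock += 1.0 / rate
    else:
        raise ValueError("time_advance must be 'exponential' or 'fixed'")

    nbr = neighbor_table(L)
    pf = state.p.ravel()
    qf = state.q.ravel()
    wf = state.w.ravel()
    bf = state.birth_time.ravel()

    is_game = rng.random() < 1.0 / (1.0 + params.R)
    focal = int(rng.integers(n))
    if is_game:
        j = int(nbr[focal, rng.integers(4)])
        state.event_counts[0] += 1
        pay_i, pay_j = play_game(
            Strategy(pf[focal], qf[focal]), Strategy(pf[j], qf[j])
        )
        if pay_i + pay_j > 0.0:
            state.event_counts[1] += 1
        wf[focal] += pay_i
        wf[j] += pay_j
    else:
        state.event_counts[2] += 1
        victim = int(nbr[focal, select_victim(wf[nbr[focal]], rng)])
        child = mutate(
            Strategy(pf[focal], qf[focal]),
            params.mu,
            rng,
            boundary=params.mutation_boundary,
        )
        pf[victim] = child.p
        qf[victim] = child.q
        wf[victim] = 0.0
        bf[victim] = state.clock
    return state


def run(
    params: ModelParams,
    init,
    t_max: float,
    sample_times,
    *,
    time_advance: str = "exponential",
    snapshot_times=(),
    p_bins: int = DEFAULT_P_BINS,
):
    """Run the model from a fresh initial state and record observables.

    Parameters
    ----------
    params
        Model parameters, including the seed for the single random stream
        driving the whole run.
    init
        An :class:`~ugevolve.initializers.InitSpec` (or an already built
        :class:`LatticeState`, which is then run as-is).
    t_max
        Final time; must be positive and at least the last sample time.
    sample_times
        Sorted, non-empty times in ``[0, t_max]`` at which the observable
        row is recorded.
    time_advance
        ``"exponential"`` (exact Gillespie; default) or ``"fixed"``.
    snapshot_times
        Times at which a full copy of the lattice arrays is taken.
    p_bins
        Resolution of the offer-binned reproduction tally used for
        fitness-landscape diagnostics.

    Returns
    -------
    series : pandas.DataFrame
        One row per sample time, columns as documented in
        :mod:`ugevolve.observables`.
    state : LatticeState
        Final state (clock at ``t_max``).
    extras : dict
        ``snapshots`` (time -> dict of copied arrays) and the
        offer-binned tallies ``repro_by_p_bin`` (reproduction events by
        parent offer), ``deaths_by_p_bin`` (by victim offer) and
        ``occupancy_by_p_bin`` (population histogram accumulated at
        sample times), each of length ``p_bins``.

    Determinism: two calls with identical arguments produce bit-identical
    outputs.
    """
    from .initializers import InitSpec, build_lattice

    sample_times = np.asarray(sample_times, dtype=np.float64)
    if sample_times.size == 0:
        raise ValueError("sample schedule must not be empty")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if np.any(np.diff(sample_times) < 0):
        raise ValueError("sample_times must be sorted")
    if sample_times[0] < 0 or sample_times[-1] > t_max:
        raise ValueError("sample_times must lie within [0, t_max]")
    if time_advance not in ("exponential", "fixed"):
        raise ValueError("time_advance must be 'exponential' or 'fixed'")

    if isinstance(init, LatticeState):
        state = init
    elif isinstance(init, InitSpec):
        state = build_lattice(init, params)
    else:
        raise TypeError("init must be an InitSpec or a LatticeState")

    nbr = neighbor_table(params.L)
    pf = state.p.ravel()
    qf = state.q.ravel()
    wf = state.w.ravel()
    bf = state.birth_time.ravel()

    out = np.empty((sample_times.size, _kernel.N_STAT), dtype=np.float64)
    repro_hist = np.zeros(p_bins, dtype=np.float64)
    death_hist = np.zeros(p_bins, dtype=np.float64)
    occ_hist = np.zeros(p_bins, dtype=np.float64)
    hw = MUTATION_HALF_WIDTH_FACTOR * params.mu
    clip_mode = params.mutation_boundary == "clip"
    fixed_dt = time_advance == "fixed"

    rng_state = _kernel.make_rng_state(params.seed % (2**31))

    snapshot_times = sorted(float(t) for t in snapshot_times)
    if snapshot_times and (snapshot_times[0] < 0 or snapshot_times[-1] > t_max):
        raise ValueError("snapshot_times must lie within [0, t_max]")
    boundaries = snapshot_times + [float(t_max)]
    snapshots = {}
    t = state.clock
    lo = 0
    for t_end in boundaries:
        hi = int(np.searchsorted(sample_times, t_end, side="right"))
        seg = sample_times[lo:hi]
        t = _kernel.run_segment(
            rng_state, pf, qf, wf, bf, nbr,
            float(params.R), hw, clip_mode, fixed_dt,
            t, t_end, seg, out[lo:hi],
            state.event_counts, repro_hist, death_hist, occ_hist,
        )
        lo = hi
        if t_end in snapshot_times:
            snapshots[t_end] = {
                "p": state.p.copy(),
                "q": state.q.copy(),
                "w": state.w.copy(),
                "birth_time": state.birth_time.copy(),
            }
    state.clock = float(t)

    from .observables import TIMESERIES_COLUMNS

    series = pd.DataFrame(out, columns=list(TIMESERIES_COLUMNS))
    extras = {
        "snapshots": snapshots,
        "repro_by_p_bin": repro_hist,
        "deaths_by_p_bin": death_hist,
        "occupancy_by_p_bin": occ_hist,
    }
    return series, state, extras
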