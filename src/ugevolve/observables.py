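"""Population statistics, time-scales, and steady-state detection.

The observable row recorded at each sample time holds population (not
sample) moments over all ``L**2`` agents: means and standard deviations
of the offer, threshold, wealth and age distributions, the first four
cumulants of the offer distribution, and the fractions of agents with
``p < q`` and with exactly zero wealth.

Equilibration of the strategy distribution is diffusive: each site turns
over ``R`` generations per unit time and each generation displaces the
lineage by a mutation of variance ``mu**2`` per coordinate, so lineages
explore the unit strategy square on the characteristic time

    tau_eq = 1 / (R * mu**2).

Steady state is declared by a block test on that same scale: the late
time series is cut into blocks of length ``tau``, consecutive block means
of the mean offer and mean threshold must agree within twice their
combined standard errors, and the steady-state estimate then treats the
block means as independent samples, with uncertainty

    sigma_M = sigma / sqrt(N - 1)

for ``N`` block means of standard deviation ``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from ._kernel import STAT_COLUMNS as TIMESERIES_COLUMNS
from .scheduler import LatticeState

__all__ = [
    "TIMESERIES_COLUMNS",
    "tau_eq",
    "summarize",
    "SteadyStateEstimate",
    "detect_steady_state",
    "log_sample_times",
]


def tau_eq(R: float, mu: float) -> float:
    """Characteristic equilibration time ``1/(R * mu**2)``.

    This is the time for mutational diffusion (at ``R`` generations per
    unit time, variance ``mu**2`` per generation and coordinate) to carry
    lineages across the unit strategy square; steady-state averaging
    requires samples separated by at least this much to be independent.

    Raises
    ------
    ValueError
        If ``R <= 0``, or if ``mu == 0`` (no mutation means the strategy
        distribution never equilibrates; the divergence is signalled
        explicitly rather than returning infinity).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if mu == 0:
        raise ValueError("mu = 0: equilibration time is infinite")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    return 1.0 / (R * mu * mu)


def summarize(state: LatticeState) -> pd.Series:
    """Observable row for the current lattice state.

    Exact population moments over all agents; offer cumulants ``k1..k4``
    via the standard central-moment conversion (``k4`` is the excess
    fourth cumulant ``m4 - 3*m2**2``, not the raw moment); ages are
    ``clock - birth_time``.
    """
    p = state.p.ravel()
    q = state.q.ravel()
    w = state.w.ravel()
    age = state.ages().ravel()
    mp = p.mean()
    d = p - mp
    m2 = np.mean(d**2)
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    g, ga, r = state.event_counts
    return pd.Series(
        {
            "t": state.clock,
            "mean_p": mp,
            "mean_q": q.mean(),
            "sd_p": np.sqrt(m2),
            "sd_q": q.std(),
            "mean_w": w.mean(),
            "sd_w": w.std(),
            "mean_age": age.mean(),
            "sd_age": age.std(),
            "k1_p": mp,
            "k2_p": m2,
            "k3_p": m3,
            "k4_p": m4 - 3.0 * m2 * m2,
            "frac_p_lt_q": np.mean(p < q),
            "frac_zero_wealth": np.mean(w == 0.0),
            "games": float(g),
            "games_accepted": float(ga),
            "reproductions": float(r),
        }
    )


@dataclass(frozen=True)
class SteadyStateEstimate:
    """Steady-state means with standard-error-of-the-mean uncertainties.

    ``sigma_M = sigma / sqrt(N - 1)`` over the ``N`` block means
    (spaced by at least the block length, itself chosen >= tau_eq so the
    samples are independent).
    """

    mean_p: float
    mean_q: float
    sigma_m_p: float
    sigma_m_q: float
    n_samples: int
    sample_spacing: float
    equilibration_time: float

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("a steady-state estimate needs at least 2 samples")

    def to_dict(self) -> dict:
        return asdict(self)


def _block_stats(sub: pd.DataFrame, col: str) -> tuple[float, float]:
    vals = sub[col].to_numpy()
    mean = vals.mean()
    if len(vals) > 1:
        sem = vals.std(ddof=0) / np.sqrt(len(vals) - 1)
    else:
        sem = 0.0
    return mean, sem


def detect_steady_state(
    series: pd.DataFrame, tau: float
) -> Optional[SteadyStateEstimate]:
    """Block test for stationarity of the mean offer and threshold.

    The series (which must span at least ``2*tau``) is cut into
    contiguous blocks of length ``tau`` anchored at its final time.
    Walking backwards from the end, blocks are accepted into the steady
    window while consecutive block means of both ``mean_p`` and
    ``mean_q`` differ by less than twice their combined standard errors.
    With at least two accepted blocks the run is declared steady and the
    block means are treated as ``N`` independent samples: the estimate is
    their mean with uncertainty ``sigma_M = sigma/sqrt(N-1)``.

    Returns ``None`` (not an exception) when the criterion fails —
    the run is not yet steady.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = series["t"].to_numpy()
    span = t[-1] - t[0]
    if span < 2 * tau:
        raise ValueError("series must span at least 2*tau")
    t_end = t[-1]
    n_blocks = int(span // tau)
    blocks = []
    for k in range(n_blocks):
        hi = t_end - k * tau
        lo = hi - tau
        sub = series[(t > lo) & (t <= hi)] if k else series[t > lo]
        if len(sub) == 0:
            break
        blocks.append(sub)
    if len(blocks) < 2:
        return None

    means_p, sems_p = zip(*(_block_stats(b, "mean_p") for b in blocks))
    means_q, sems_q = zip(*(_block_stats(b, "mean_q") for b in blocks))

    n_ok = 1
    for k in range(len(blocks) - 1):
        tol_p = 2.0 * np.hypot(sems_p[k], sems_p[k + 1])
        tol_q = 2.0 * np.hypot(sems_q[k], sems_q[k + 1])
        if (
            abs(means_p[k] - means_p[k + 1]) < tol_p
            and abs(means_q[k] - means_q[k + 1]) < tol_q
        ):
            n_ok += 1
        else:
            break
    if n_ok < 2:
        return None

    bp = np.array(means_p[:n_ok])
    bq = np.array(means_q[:n_ok])
    n = n_ok
    return SteadyStateEstimate(
        mean_p=float(bp.mean()),
        mean_q=float(bq.mean()),
        sigma_m_p=float(bp.std(ddof=0) / np.sqrt(n - 1)),
        sigma_m_q=float(bq.std(ddof=0) / np.sqrt(n - 1)),
        n_samples=n,
        sample_spacing=float(tau),
        equilibration_time=float(t_end - n_ok * tau),
    )


def log_sample_times(
    t_max: float, per_decade: int = 20, t_min: Optional[float] = None
) -> np.ndarray:
    """Logarithmically spaced sample schedule from ``t_min`` to ``t_max``.

    Relaxation spans several decades (ageing on the ``1/R`` scale,
    strategy equilibration on the ``tau_eq`` scale), so samples are laid
    out uniformly in log time, with ``t = 0`` prepended to capture the
    initial state.  Default ``t_min`` is four decades below ``t_max``.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if t_min is None:
        t_min = t_max / 1e4
    if not 0 < t_min < t_max:
        raise ValueError("t_min must lie in (0, t_max)")
    n = max(2, int(np.ceil(per_decade * np.log10(t_max / t_min))) + 1)
    times = np.geomspace(t_min, t_max, n)
    times[-1] = t_max
    return np.concatenate([[0.0], times])
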