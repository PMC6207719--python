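"""Survival probabilities when pay-offs are rare.

When death (rate ``R``) is much faster than gaming (unit rate), most
agents die having never played, so the population wealth distribution is
*zero-inflated*: a large atom at ``w = 0`` plus a small probability
``epsilon`` of any non-zero wealth.  In a competition among ``z``
neighbours of which exactly one dies, an agent's survival probability is
some kernel ``K(w, {w_i})`` of its wealth and its competitors'.  Because
exactly one agent dies, every kernel obeys the sum rule

    sum_j [1 - K(w_j, {w_i : i != j})] = 1,

whence ``K(a, {a, ..., a}) = 1 - 1/z`` for any common wealth ``a``.  For
*scale-free* kernels — those depending only on the wealth ordering or on
wealth ratios, not on magnitudes — the survival probability of the sole
rich agent in an otherwise penniless neighbourhood is a constant
``lambda = K(w, {0, ..., 0})`` independent of ``w``, and expanding the
exact survival rate to first order in the non-zero-wealth probabilities
gives the closed form

    P(s) = 1 - 1/z + (eps_s - eps'_s) * (lambda - 1 + 1/z),

which depends on the wealth distributions only through the difference of
their zero-avoidance probabilities.  Fitness at high death rate is
therefore risk-minimisation — avoid having nothing — not income
maximisation.

This module provides the kernel library, exact enumeration and
Monte-Carlo evaluation of the survival rate, the first-order closed form
and its model-free bounds, plus the interface success-count enumeration
and the well-mixed generous-population results used to analyse the
lattice model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "SurvivalKernel",
    "ZeroInflatedWealth",
    "KERNELS",
    "make_kernel",
    "survival_probability_exact",
    "survival_probability_first_order",
    "survival_probability_mc",
    "survival_probability_bounds",
    "NotScaleFreeError",
    "interface_success_counts",
    "well_mixed_generous_mean",
    "generous_acceptance_probability",
]

#: Cap on the number of terms enumerated by the exact survival sum.
EXACT_ENUMERATION_CAP = 2_000_000


class NotScaleFreeError(ValueError):
    """Raised when the first-order closed form is requested for a kernel
    with an intrinsic wealth scale; only the model-free bounds
    ``P1 = 1 - 1/z`` and ``P2 = 1 - 1/z + (eps_s - eps'_s)/z`` apply."""


@dataclass(frozen=True)
class SurvivalKernel:
    """A competition scheme for a neighbourhood of ``z`` agents.

    ``death_probs`` maps a wealth vector of length ``z`` to the
    probability that each agent is the one killed; the probabilities sum
    to one by construction, which is exactly the sum rule above.  Random
    tie-breaks are averaged analytically, so the rule holds to machine
    precision.

    ``survival_batch`` is a vectorised survival probability of the focal
    (column 0) agent over rows of wealth vectors, used by the Monte-Carlo
    evaluator.
    """

    name: str
    death_probs: Callable[[np.ndarray], np.ndarray]
    survival_batch: Callable[[np.ndarray], np.ndarray]
    scale_free: bool
    alpha: Optional[float] = None

    def survival(self, w: float, competitors) -> float:
        """``K(w, {w_i})``: survival probability of an agent of wealth
        ``w`` among the given competitors (``z = 1 + len(competitors)``)."""
        vec = np.concatenate([[w], np.asarray(competitors, dtype=float)])
        return 1.0 - float(self.death_probs(vec)[0])

    def lambda_const(self, z: int) -> float:
        """``K(w, {0,...,0})`` for ``w > 0``.  For scale-free kernels this
        is the constant of the first-order theorem (computed from the
        kernel definition, never assumed)."""
        return self.survival(1.0, np.zeros(z - 1))


# --- kernel library ---------------------------------------------------------

def _box1_death(w: np.ndarray) -> np.ndarray:
    # Half the time a uniformly random agent dies; half the time the
    # poorest dies, ties split evenly.
    z = w.size
    d = np.full(z, 0.5 / z)
    poorest = w == w.min()
    d[poorest] += 0.5 / poorest.sum()
    return d


def _box1_surv_batch(W: np.ndarray) -> np.ndarray:
    z = W.shape[1]
    wmin = W.min(axis=1)
    n_poor = (W == wmin[:, None]).sum(axis=1)
    focal_poor = W[:, 0] == wmin
    return 1.0 - (0.5 / z + 0.5 * focal_poor / n_poor)


def _iib_weights(w: np.ndarray) -> np.ndarray:
    # pairwise comparisons: an agent accrues death weight 1 against each
    # strictly richer competitor, 1/2 against each equal one.
    richer = (w[None, :] > w[:, None]).sum(axis=1)
    equal = (w[None, :] == w[:, None]).sum(axis=1) - 1
    return richer + 0.5 * equal


def _iib_death(w: np.ndarray) -> np.ndarray:
    z = w.size
    return _iib_weights(w) / (z * (z - 1) / 2.0)


def _iib_surv_batch(W: np.ndarray) -> np.ndarray:
    z = W.shape[1]
    w0 = W[:, 0][:, None]
    richer = (W > w0).sum(axis=1)
    equal = (W == w0).sum(axis=1) - 1
    return 1.0 - (richer + 0.5 * equal) / (z * (z - 1) / 2.0)


def _replicator_death(w: np.ndarray) -> np.ndarray:
    z = w.size
    gap = w.max() - w
    s = gap.sum()
    if s == 0.0:
        return np.full(z, 1.0 / z)
    return gap / s


def _replicator_surv_batch(W: np.ndarray) -> np.ndarray:
    wmax = W.max(axis=1)
    gap0 = wmax - W[:, 0]
    s = (wmax[:, None] - W).sum(axis=1)
    out = np.full(W.shape[0], 1.0 - 1.0 / W.shape[1])
    nz = s > 0
    out[nz] = 1.0 - gap0[nz] / s[nz]
    return out


def _ranked_death(w: np.ndarray) -> np.ndarray:
    # death weight linear in wealth rank; ties get the averaged rank.
    z = w.size
    r = z - rankdata(w, method="average")
    return 2.0 * r / (z * (z - 1))


def _ranked_surv_batch(W: np.ndarray) -> np.ndarray:
    z = W.shape[1]
    r = z - rankdata(W, method="average", axis=1)[:, 0]
    return 1.0 - 2.0 * r / (z * (z - 1))


def _linear_death(w: np.ndarray) -> np.ndarray:
    # survival proportional to wealth, K_j = (z-1) w_j / sum(w).  The sum
    # rule holds identically, but the entries are true probabilities only
    # while no agent holds more than 1/(z-1) of the total wealth.
    z = w.size
    s = w.sum()
    if s == 0.0:
        return np.full(z, 1.0 / z)
    return 1.0 - (z - 1) * w / s


def _linear_surv_batch(W: np.ndarray) -> np.ndarray:
    z = W.shape[1]
    s = W.sum(axis=1)
    out = np.full(W.shape[0], 1.0 - 1.0 / z)
    nz = s > 0
    out[nz] = (z - 1) * W[nz, 0] / s[nz]
    return out


def _fermi_death(alpha: float):
    def death(w: np.ndarray) -> np.ndarray:
        z = w.size
        f = 1.0 / (1.0 + np.exp((w[:, None] - w[None, :]) / alpha))
        np.fill_diagonal(f, 0.0)
        return f.sum(axis=1) / (z * (z - 1) / 2.0)

    return death


def _fermi_surv_batch(alpha: float):
    def batch(W: np.ndarray) -> np.ndarray:
        z = W.shape[1]
        f = 1.0 / (1.0 + np.exp((W[:, 0][:, None] - W[:, 1:]) / alpha))
        return 1.0 - f.sum(axis=1) / (z * (z - 1) / 2.0)

    return batch


def make_kernel(name: str, alpha: Optional[float] = None) -> SurvivalKernel:
    """Construct a kernel from the library by name.

    Available: ``box1`` (half random, half poorest-dies with random
    tie-break — the lattice model's own rule), ``imitate_if_better``
    (pairwise comparisons, richer survives), ``replicator`` (death
    probability proportional to the wealth gap to the richest),
    ``ranked`` (death weight linear in wealth rank), ``linear``
    (survival proportional to wealth share), and ``smoothed_imitation``
    (pairwise Fermi comparisons at wealth scale ``alpha``; the only
    kernel with an intrinsic scale).
    """
    if name == "smoothed_imitation":
        if alpha is None or alpha <= 0:
            raise ValueError("smoothed_imitation requires a positive alpha")
        return SurvivalKernel(
            name, _fermi_death(alpha), _fermi_surv_batch(alpha),
            scale_free=False, alpha=alpha,
        )
    table = {
        "box1": (_box1_death, _box1_surv_batch),
        "imitate_if_better": (_iib_death, _iib_surv_batch),
        "replicator": (_replicator_death, _replicator_surv_batch),
        "ranked": (_ranked_death, _ranked_surv_batch),
        "linear": (_linear_death, _linear_surv_batch),
    }
    if name not in table:
        raise ValueError(f"unknown kernel {name!r}; choose from "
                         f"{sorted(table) + ['smoothed_imitation']}")
    death, batch = table[name]
    return SurvivalKernel(name, death, batch, scale_free=True)


#: All library kernels at default parameters (Fermi scale alpha = 1).
KERNELS = {
    name: make_kernel(name)
    for name in ("box1", "imitate_if_better", "replicator", "ranked", "linear")
}
KERNELS["smoothed_imitation"] = make_kernel("smoothed_imitation", alpha=1.0)


# --- zero-inflated wealth distributions -------------------------------------

@dataclass(frozen=True)
class ZeroInflatedWealth:
    """Discrete wealth law ``(1 - eps) * delta(w) + eps * fhat(w)``.

    ``eps`` is the total probability of any non-zero wealth; ``fhat`` is
    the normalized distribution of the paid minority, supported on
    strictly positive values.
    """

    epsilon: float
    values: tuple
    probs: tuple

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        v = np.asarray(self.values, dtype=float)
        pr = np.asarray(self.probs, dtype=float)
        if v.shape != pr.shape or v.ndim != 1 or v.size == 0:
            raise ValueError("values and probs must be matching 1-d sequences")
        if np.any(v <= 0):
            raise ValueError("non-zero part must have strictly positive support")
        if np.any(pr < 0) or not np.isclose(pr.sum(), 1.0):
            raise ValueError("fhat probabilities must be non-negative and sum to 1")

    @classmethod
    def atom(cls, epsilon: float, value: float) -> "ZeroInflatedWealth":
        """All paid agents hold the same wealth ``value``."""
        return cls(epsilon, (float(value),), (1.0,))

    def full_support(self) -> tuple[np.ndarray, np.ndarray]:
        """Support and probabilities including the zero atom."""
        v = np.concatenate([[0.0], np.asarray(self.values, dtype=float)])
        pr = np.concatenate(
            [[1.0 - self.epsilon],
             self.epsilon * np.asarray(self.probs, dtype=float)]
        )
        return v, pr

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        v, pr = self.full_support()
        return rng.choice(v, size=n, p=pr)


# --- survival-rate evaluators ------------------------------------------------

def survival_probability_exact(
    kernel: SurvivalKernel,
    own: ZeroInflatedWealth,
    competitor: ZeroInflatedWealth,
    z: int,
) -> float:
    """Exact survival rate by enumeration of the full product space.

    Sums ``K(w, {w_i}) f(w) prod_j g(w_j)`` over the own-wealth support
    and all ``z - 1`` independent competitor draws.  Supports whose
    product space exceeds :data:`EXACT_ENUMERATION_CAP` terms are
    rejected; use :func:`survival_probability_mc` for those.
    """
    if z < 2:
        raise ValueError("a competition needs z >= 2 agents")
    ov, op = own.full_support()
    cv, cp = competitor.full_support()
    n_terms = ov.size * cv.size ** (z - 1)
    if n_terms > EXACT_ENUMERATION_CAP:
        raise ValueError(
            f"exact enumeration would need {n_terms} terms "
            f"(cap {EXACT_ENUMERATION_CAP}); use survival_probability_mc"
        )
    total = 0.0
    for combo in itertools.product(range(cv.size), repeat=z - 1):
        comp_w = cv[list(combo)]
        comp_p = np.prod(cp[list(combo)])
        for i in range(ov.size):
            k = kernel.survival(ov[i], comp_w)
            total += k * op[i] * comp_p
    return total


def survival_probability_first_order(
    kernel: SurvivalKernel, eps_s: float, eps_prime_s: float, z: int
) -> float:
    """First-order closed form for scale-free kernels.

    ``P(s) = 1 - 1/z + (eps_s - eps'_s) * (lambda - 1 + 1/z)`` with
    ``lambda`` computed from the kernel definition.  The survival rate
    depends on the wealth distributions only through the difference of
    their zero-avoidance probabilities — pay-off magnitudes are
    irrelevant to first order.
    """
    if z < 2:
        raise ValueError("a competition needs z >= 2 agents")
    for name, val in (("eps_s", eps_s), ("eps_prime_s", eps_prime_s)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if not kernel.scale_free:
        p1, p2 = survival_probability_bounds(eps_s, eps_prime_s, z)
        raise NotScaleFreeError(
            f"kernel {kernel.name!r} has an intrinsic wealth scale; the "
            f"first-order closed form does not apply. Model-free bounds: "
            f"P1 = {p1}, P2 = {p2}."
        )
    lam = kernel.lambda_const(z)
    return 1.0 - 1.0 / z + (eps_s - eps_prime_s) * (lam - 1.0 + 1.0 / z)


def survival_probability_bounds(
    eps_s: float, eps_prime_s: float, z: int
) -> tuple[float, float]:
    """Model-free first-order bounds ``(P1, P2)`` valid for any kernel:
    ``P1 = 1 - 1/z`` and ``P2 = 1 - 1/z + (eps_s - eps'_s)/z``."""
    if z < 2:
        raise ValueError("a competition needs z >= 2 agents")
    p1 = 1.0 - 1.0 / z
    return p1, p1 + (eps_s - eps_prime_s) / z


def survival_probability_mc(
    kernel: SurvivalKernel,
    own: ZeroInflatedWealth,
    competitor: ZeroInflatedWealth,
    z: int,
    n_draws: int = 1_000_000,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Monte-Carlo survival rate: mean and standard error.

    Draws the focal wealth from ``own`` and ``z - 1`` competitor wealths
    independently from ``competitor``, and averages the kernel's focal
    survival probability.  Serves as the stochastic oracle for supports
    too large to enumerate (and as an independent check on the exact
    enumerator).
    """
    if z < 2:
        raise ValueError("a competition needs z >= 2 agents")
    rng = np.random.default_rng() if rng is None else rng
    W = np.empty((n_draws, z))
    W[:, 0] = own.sample(n_draws, rng)
    W[:, 1:] = competitor.sample(n_draws * (z - 1), rng).reshape(n_draws, z - 1)
    k = kernel.survival_batch(W)
    return float(k.mean()), float(k.std(ddof=1) / np.sqrt(n_draws))


# --- interface enumeration and well-mixed results ----------------------------

def interface_success_counts(focal, neighbors) -> int:
    """Number of the focal agent's eight possible games paying it > 0.

    Each agent can play each of its four neighbours as proposer or as
    responder — eight distinct games.  As proposer the focal agent is
    paid ``1 - p`` when its offer is accepted (``p >= q_neighbour``), so
    success additionally requires ``p < 1``; as responder it is paid the
    neighbour's offer when accepted (``p_neighbour >= q``), so success
    requires ``p_neighbour > 0``.  At high death rate this count — not
    any pay-off magnitude — sets relative fitness.
    """
    neighbors = list(neighbors)
    if len(neighbors) != 4:
        raise ValueError("exactly four neighbours required")
    fp, fq = focal[0], focal[1]
    count = 0
    for nb in neighbors:
        np_, nq = nb[0], nb[1]
        if fp >= nq and fp < 1.0:
            count += 1
        if np_ >= fq and np_ > 0.0:
            count += 1
    return count


def well_mixed_generous_mean() -> float:
    """Mean offer of a well-mixed generous population.

    A population whose strategies uniformly fill ``p in (1/2, 1]``,
    ``q in [0, 1/2)`` never has an offer rejected (``p > q`` in every
    pairing), and its mean offer is exactly 3/4.  Such a population is
    stochastically stable at high death rate: a greedier mutant raises
    its conditional pay-off but lowers its acceptance — and hence
    zero-avoidance — probability, so it cannot invade.
    """
    return 0.75


def generous_acceptance_probability(p_mutant: float) -> float:
    """Probability that the generous population accepts an offer.

    Responders' thresholds are uniform on ``[0, 1/2]``, so an offer
    ``p'`` is accepted with probability ``min(2 p', 1)``.
    """
    if not 0.0 <= p_mutant <= 1.0:
        raise ValueError("offer must lie in [0, 1]")
    return min(2.0 * p_mutant, 1.0)
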