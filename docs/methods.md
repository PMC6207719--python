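# Methods

## The model

Agents occupy an `L x L` square lattice with periodic boundaries and
von Neumann (4-neighbour) connectivity.  Each agent `i` carries an
unchanging strategy `s_i = (p_i, q_i)` for the Ultimatum Game — the
fraction `p_i` it offers when proposing and the minimum offer `q_i` it
accepts when responding — plus its accumulated wealth `w_i >= 0` and its
birth time.

Three stochastic processes drive the dynamics:

* **Gaming** (unit rate per agent; this sets the time unit).  A uniformly
  chosen agent proposes to a uniformly chosen nearest neighbour `j`.  If
  `p_i >= q_j` (inclusive) the responder is paid `p_i` and the proposer
  keeps `1 - p_i`; otherwise neither is paid.  The proposer is never
  debited: each accepted game injects one unit of exogenous resource,
  split between the pair.
* **Competition and reproduction** (rate `R` per agent).  A uniformly
  chosen agent reproduces asexually into one of its four neighbours,
  killing the occupant.  Half the time the victim is the poorest
  neighbour (exact wealth ties broken uniformly — ties effectively occur
  only at `w = 0`, among agents that have never been paid); half the time
  the victim is uniform regardless of wealth.  The offspring starts with
  wealth exactly 0 and strategy `(p + dp, q + dq)`, each perturbation
  drawn from the zero-mean uniform law with standard deviation `mu`
  (half-width `sqrt(3)*mu`), subject to the coordinate staying in [0, 1].

Because each reproduction kills exactly one neighbour, the population is
exactly `L**2` forever.

### Scheduling

The process is simulated exactly (Gillespie): the total event rate is
`L**2 * (1 + R)`, waiting times are exponential with that rate, and each
event is a game with probability `1/(1+R)`, else a reproduction.  Events
are applied strictly sequentially (asynchronous updating).  A
fixed-increment mode (`dt = 1/(L**2 (1+R))`) is provided for comparison;
at the event counts involved the two are statistically indistinguishable,
but exactness is preferred as the default.

Randomness for a run comes from a single explicit xoshiro256** stream
seeded (via splitmix64) from the model seed, with a documented draw order
per event (see `_kernel.py`), so runs are reproducible bit-for-bit.  The
builtin numba generator was measured several times slower, which matters
at the ~10^9-event scale of the longer runs.  Initial strategy fields use
a numpy `Generator` seeded from the same model seed.  The pure-Python
`step()` reference path uses the numpy stream; it implements the same
process and is cross-checked statistically against the compiled loop.

### Boundary handling of mutation

The mutation law fixes the distribution (uniform, SD `mu`) but not
how the [0, 1] constraint is enforced.  Default is per-component
rejection resampling, which preserves the uniform shape on the admissible
set; clipping (which creates atoms at 0 and 1) is available as
`mutation_boundary="clip"` for sensitivity checks.  Near a boundary any
bounded rule biases the perturbation inward; with the production-scale
`mu ~ 0.003` the boundary band is ~0.005 wide and the choice is
immaterial in practice.  Mutation components are drawn independently
(p first, then q).

## Initial conditions

* `random_uniform`: `p, q ~ U[0,1]` independently at every site — no
  preconception about the final state.
* `half_and_half`: columns `x < L/2` archetypally selfish
  `(p, q) = (0, 0)`; columns `x >= L/2` maximally generous (`p = 1`,
  `q ~ U[0,1]`), giving two straight vertical interfaces (one at the
  periodic boundary).  Both halves lie in the closed dominant triangle
  `q <= p`.  Used to demonstrate independence of the steady state from
  the start.  Requires even `L`.
* `monomorphic`: a single strategy everywhere (testing).

Founders are treated like newborns (wealth 0, birth time 0), so the
early-time mean age grows like the clock itself before saturating at
`1/R`.

## Observables

Each sample records exact population (not sample) moments over all
`L**2` agents: mean/SD of offers, thresholds, wealth and age, the first
four cumulants of the offer distribution (`k4` is the excess cumulant
`m4 - 3 m2^2`), the fraction of agents with `p < q`, and the fraction
with exactly zero wealth.  Ages are `clock - birth_time`.

Two time-scales organise the dynamics.  Demography equilibrates on
`1/R`.  The strategy distribution equilibrates by mutational diffusion:
`R` generations per site per unit time, each displacing a lineage by
variance `mu^2` per coordinate, gives the characteristic time

    tau_eq = 1 / (R * mu^2),

the time to explore the unit strategy square.  `tau_eq` is rejected for
`mu = 0` (no mutation: infinite).

### Steady-state detection

Stationarity in this kind of model is conventionally judged
qualitatively (statistics "asymptoting"); the operational rule used here
is a block test on the `tau_eq` scale: the late series is cut into
blocks of length `tau` anchored at the final time; walking backwards,
blocks are accepted while consecutive block means of both the mean offer
and mean threshold agree within twice their combined within-block
standard errors; with >= 2 accepted blocks the estimate is the mean of
the block means with uncertainty `sigma_M = sigma/sqrt(N-1)` (the block
means, spaced `tau >= tau_eq`, are treated as independent).  Failure
returns "not yet steady" (None), not an exception.  Within-block samples
closer than `tau` are correlated, so the within-block SEM understates the
block-mean error; this makes the gate conservative (it declares
steadiness late rather than early).

## Survival calculus at high death rate

When `R >> 1` most agents die having never played, so wealth
distributions are zero-inflated: `f(w) = (1-eps) delta(w) + eps fhat(w)`
with `fhat(0) = 0`.  A competition among `z` agents kills exactly one;
survival kernels `K(w, {w_i})` therefore obey the sum rule
`sum_j [1 - K_j] = 1` and its corollaries `K(a, {a..a}) = 1 - 1/z` and
the one-rich/rest-equal balance identity.  The kernel library implements
each scheme as a normalized vector of death probabilities (random
tie-breaks averaged analytically, so the sum rule is exact to machine
precision):

| name | rule | scale-free | lambda(z=4) |
|---|---|---|---|
| `box1` | half uniform, half poorest-dies (ties split) — the lattice model's own rule | yes | 7/8 |
| `imitate_if_better` | pairwise comparisons, richer survives | yes | 1 |
| `replicator` | death probability proportional to the wealth gap to the richest | yes | 1 |
| `ranked` | death weight linear in wealth rank (ties averaged) | yes | 1 |
| `linear` | survival proportional to wealth share, `K_j = (z-1) w_j / sum w` | yes | z-1 |
| `smoothed_imitation` | pairwise Fermi comparisons at wealth scale `alpha` | no | — |

`lambda = K(w>0, {0,..,0})` is computed from the kernel definition,
never assumed.  The `linear` kernel is implemented exactly as commonly
written; its entries are genuine probabilities only while no agent holds
more than `1/(z-1)` of the neighbourhood total (the sum rule and the
balance identity hold algebraically regardless), and its `lambda = z-1`
lies outside [1-1/z, 1] — a caveat documented in its docstring.

Three routes to the survival rate `P(s)` of a strategy with
zero-avoidance probability `eps` against competitors with `eps'`:

1. exact enumeration of the full product space (capped at 2e6 terms);
2. a vectorised Monte-Carlo estimator (mean and standard error);
3. the first-order closed form for scale-free kernels,
   `P = 1 - 1/z + (eps - eps') (lambda - 1 + 1/z)`,
   which depends on the wealth laws only through `eps - eps'`.  For
   kernels with an intrinsic wealth scale this form is refused and the
   model-free bounds `P1 = 1-1/z`, `P2 = 1-1/z + (eps-eps')/z` reported
   instead.

The tests verify that routes 1 and 2 agree within Monte-Carlo error,
that 1 and 3 differ by `O(eps^2)` (fitted log-log slope >= 2), and that
survival is insensitive to pay-off magnitude at fixed `eps` — the
risk-not-income principle.  For kernels whose death weight is a sum of
pairwise comparisons (`imitate_if_better`, `ranked`) the exact rate is
linear in the joint pair probabilities, so the "first-order" form can be
exact for some distribution pairs; the quadratic-scaling test uses
supports that interleave the two distributions to avoid that degeneracy.

Companion analytic results: the interface success-count enumeration
(eight games per agent; a success must pay the focal agent strictly more
than zero, which excludes the proposer at `p = 1` and the responder at
`p = 0`), and the well-mixed generous population (strategies uniform on
`p in (1/2, 1]`, `q in [0, 1/2)`) with mean offer exactly 3/4 and
acceptance probability `min(2p', 1)` for a mutant offer `p'`.

## Problem sizes and study conditions

Defaults reproduce the published parameter points; lattice sizes are
chosen per quantity:

* **Steady state at (R, mu) = (80, 0.00462)** (`tau_eq ~ 586`): two
  independent replicates at L = 64, each run to `20 tau_eq`, pooling the
  38 instantaneous samples spaced `tau_eq` (burn-in `2 tau_eq`).  At
  L = 64 the instantaneous population mean offer fluctuates with
  SD ~ 0.1 and wanders on a time-scale of a few hundred time units (the
  correlation length is a sizeable fraction of the lattice), so the
  total averaging window — helped by independent replicates — is what
  buys a ~0.02 standard error; lattice size is the expensive knob.
* **Transient plateau**: evaluated at (15, 0.0015), L = 512 — the size
  at which the plateau is reported.  The plateau is a genuine but gentle
  drift (mean offer ~ 0.67 at t = 5 rising to ~ 0.71 by t = 50); at
  L <= 128 transient fluctuations add a systematic upward excess of
  0.03–0.07 to the window mean, so small lattices distort precisely this
  observable (measured here by varying L from 64 to 512).
* **Triangle absorption at (31, 0.00462)**: evaluated at L = 128
  (the published population for this observable, 16384 agents).  The
  self-defeating fraction (`p < q`) decays from 50% to the 1% level on a
  time-scale of ~10 time units; at this largest production `mu` a
  mutation-load floor of 0.3–0.6% of near-diagonal newborns persists
  indefinitely, so the measured 1% crossing sits at t ~ 12–16 rather
  than t ~ 10 (at the smaller mu = 0.0015 the crossing is at t ~ 10).
* **Rate/demography checks**: L = 32, seconds.
* **Initialization independence at (100, 0.00258)**: L = 64 to
  `4 tau_eq` from both initializations.  L = 64 is below the
  size-invariance threshold at this point (the population is
  quasi-monomorphic and the mean offer wanders), which the comparison
  tolerates because the block uncertainties grow correspondingly.

What the model does and does not emulate: agents are immobile, the
lattice is regular, pay-offs are the only resource, and strategies are
inherited with mutation but never learned.  Passing tests show the
implementation reproduces the published statistical behaviour of this
idealised process at the sizes above; they do not show anything about
larger lattices beyond the size-invariance points actually measured, nor
about the deferred model variants (non-cumulative pay-offs, competitive
births).

## Numerical choices

* Wealth ties in victim selection use exact float equality (ties arise
  at `w = 0`, where equality is exact by construction).
* Acceptance is inclusive (`p >= q`); equality accepts.
* Population moments divide by `L**2` (the whole population is
  observed), not `L**2 - 1`.
* Exact survival enumeration refuses product spaces above 2e6 terms and
  points the caller to the Monte-Carlo estimator.
* Sample schedules are logarithmic by default (20 per decade) because
  relaxation spans decades; steady-state averaging uses linear
  `tau_eq`-spaced samples.
* Uncertainties are stored at full precision and rounded only for
  display.
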