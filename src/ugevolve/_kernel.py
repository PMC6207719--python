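"""Compiled event loop for the lattice simulation.

The dynamics are a continuous-time Markov process: each of the ``n = L**2``
agents proposes games at unit rate and reproduces at rate ``R``, so the
total event rate is ``n*(1+R)`` and each elementary event is a game with
probability ``1/(1+R)`` or a reproduction with probability ``R/(1+R)``.
The loop below applies one event at a time (asynchronous updating) and is
compiled with numba; it mirrors exactly the pure-Python rules in
:mod:`ugevolve.model_core`, which the tests cross-check against it.

Randomness comes from one explicit xoshiro256** stream per run, seeded
from the model seed via splitmix64.  The stream state lives in a plain
uint64 array owned by the caller, so a run is reproducible bit-for-bit
and segments (between snapshots) continue the same stream.  Draw order
per event: waiting time, event-type uniform, focal-agent index, then the
branch-specific draws — game: neighbour index; reproduction: victim-mode
uniform, victim index (random mode) or tie-break uniforms (poorest mode,
one per tie encountered), then mutation draws for p then q (resampling
mode may consume extra draws per coordinate).
"""

import numpy as np
from numba import njit, uint64

#: Column order of the per-sample statistics block.
STAT_COLUMNS = (
    "t",
    "mean_p", "mean_q", "sd_p", "sd_q",
    "mean_w", "sd_w", "mean_age", "sd_age",
    "k1_p", "k2_p", "k3_p", "k4_p",
    "frac_p_lt_q", "frac_zero_wealth",
    "games", "games_accepted", "reproductions",
)
N_STAT = len(STAT_COLUMNS)

_DOUBLE_SCALE = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True)
def make_rng_state(seed):
    """Expand an integer seed into xoshiro256** state via splitmix64."""
    s = np.empty(4, dtype=np.uint64)
    x = uint64(seed)
    for i in range(4):
        x = x + uint64(0x9E3779B97F4A7C15)
        z = x
        z = (z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)
        s[i] = z ^ (z >> uint64(31))
    return s


@njit(cache=True, inline="always")
def _next_u64(s):
    x1 = s[1]
    r = x1 * uint64(5)
    r = ((r << uint64(7)) | (r >> uint64(57))) * uint64(9)
    t = x1 << uint64(17)
    s[2] ^= s[0]
    s[3] ^= x1
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    x3 = s[3]
    s[3] = (x3 << uint64(45)) | (x3 >> uint64(19))
    return r


@njit(cache=True, inline="always")
def _uniform(s):
    return (_next_u64(s) >> uint64(11)) * _DOUBLE_SCALE


@njit(cache=True, inline="always")
def _randint(s, k):
    # floor(u*k); modulo bias is at most k * 2**-53, negligible for the
    # lattice sizes used here.
    return int(_uniform(s) * k)


@njit(cache=True)
def _record(row, t_s, p, q, w, birth, counts):
    n = p.size
    sp = sq = sw = sa = 0.0
    for i in range(n):
        sp += p[i]
        sq += q[i]
        sw += w[i]
        sa += t_s - birth[i]
    mp = sp / n
    mq = sq / n
    mw = sw / n
    ma = sa / n
    m2p = m3p = m4p = 0.0
    vq = vw = va = 0.0
    n_lt = 0
    n_zero = 0
    for i in range(n):
        d = p[i] - mp
        d2 = d * d
        m2p += d2
        m3p += d2 * d
        m4p += d2 * d2
        dq = q[i] - mq
        vq += dq * dq
        dw = w[i] - mw
        vw += dw * dw
        da = (t_s - birth[i]) - ma
        va += da * da
        if p[i] < q[i]:
            n_lt += 1
        if w[i] == 0.0:
            n_zero += 1
    m2p /= n
    m3p /= n
    m4p /= n
    row[0] = t_s
    row[1] = mp
    row[2] = mq
    row[3] = np.sqrt(m2p)
    row[4] = np.sqrt(vq / n)
    row[5] = mw
    row[6] = np.sqrt(vw / n)
    row[7] = ma
    row[8] = np.sqrt(va / n)
    row[9] = mp
    row[10] = m2p
    row[11] = m3p
    row[12] = m4p - 3.0 * m2p * m2p
    row[13] = n_lt / n
    row[14] = n_zero / n
    row[15] = counts[0]
    row[16] = counts[1]
    row[17] = counts[2]


@njit(cache=True, inline="always")
def _mutate_coord(s, x, hw, clip_mode):
    if hw <= 0.0:
        return x
    if clip_mode:
        c = x + (2.0 * _uniform(s) - 1.0) * hw
        if c < 0.0:
            return 0.0
        if c > 1.0:
            return 1.0
        return c
    while True:
        c = x + (2.0 * _uniform(s) - 1.0) * hw
        if 0.0 <= c <= 1.0:
            return c


@njit(cache=True)
def run_segment(rng_state, p, q, w, birth, nbr, R, hw, clip_mode, fixed_dt,
                t0, t_end, sample_times, out, counts,
                repro_hist, death_hist, occ_hist):
    """Advance the lattice from t0 to t_end, recording at sample_times.

    Mutates p, q, w, birth, counts, repro_hist, occ_hist and rng_state in
    place and fills one row of ``out`` per sample time.  Returns the
    final clock.  ``repro_hist`` accumulates reproduction events binned
    by the parent's offer and ``death_hist`` by the victim's offer;
    ``occ_hist`` accumulates the population offer histogram at each
    sample time (for per-capita normalisation of both).  Parents are
    chosen uniformly, so any offer-dependence of fitness shows up in the
    per-capita death rate, not the birth rate.
    """
    n = p.size
    rate = n * (1.0 + R)
    mean_dt = 1.0 / rate
    p_game = 1.0 / (1.0 + R)
    nbins = repro_hist.size
    ns = sample_times.size
    t = t0
    si = 0
    while True:
        if fixed_dt:
            dt = mean_dt
        else:
            dt = -np.log(_uniform(rng_state) + 5e-324) * mean_dt
        t_next = t + dt
        lim = t_next if t_next < t_end else t_end
        while si < ns and sample_times[si] <= lim:
            _record(out[si], sample_times[si], p, q, w, birth, counts)
            for i in range(n):
                b = int(p[i] * nbins)
                if b == nbins:
                    b -= 1
                occ_hist[b] += 1.0
            si += 1
        if t_next >= t_end:
            return t_end
        t = t_next
        u = _uniform(rng_state)
        focal = _randint(rng_state, n)
        if u < p_game:
            j = nbr[focal, _randint(rng_state, 4)]
            counts[0] += 1
            if p[focal] >= q[j]:
                counts[1] += 1
                w[focal] += 1.0 - p[focal]
                w[j] += p[focal]
        else:
            counts[2] += 1
            if _uniform(rng_state) < 0.5:
                victim = nbr[focal, _randint(rng_state, 4)]
            else:
                victim = nbr[focal, 0]
                wmin = w[victim]
                n_tied = 1
                for k in range(1, 4):
                    cand = nbr[focal, k]
                    wk = w[cand]
                    if wk < wmin:
                        wmin = wk
                        victim = cand
                        n_tied = 1
                    elif wk == wmin:
                        n_tied += 1
                        if _uniform(rng_state) * n_tied < 1.0:
                            victim = cand
            b = int(p[focal] * nbins)
            if b == nbins:
                b -= 1
            repro_hist[b] += 1.0
            b = int(p[victim] * nbins)
            if b == nbins:
                b -= 1
            death_hist[b] += 1.0
            p[victim] = _mutate_coord(rng_state, p[focal], hw, clip_mode)
            q[victim] = _mutate_coord(rng_state, q[focal], hw, clip_mode)
            w[victim] = 0.0
            birth[victim] = t
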