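"""Tests of the rare-pay-off survival calculus.

The exact enumerator, the Monte-Carlo oracle and the first-order closed
form are three independent routes to the survival rate; they must agree
in their overlapping domains of validity.
"""

import numpy as np
import pytest

from ugevolve import (
    KERNELS,
    NotScaleFreeError,
    Strategy,
    ZeroInflatedWealth,
    generous_acceptance_probability,
    interface_success_counts,
    make_kernel,
    survival_probability_bounds,
    survival_probability_exact,
    survival_probability_first_order,
    survival_probability_mc,
    well_mixed_generous_mean,
)

WEALTH_POOL = np.array([0.0, 0.0, 0.1, 0.5, 1.0, 1.0, 2.5, 7.0])


def random_wealth_vectors(n, rng):
    for _ in range(n):
        z = int(rng.integers(2, 7))
        yield rng.choice(WEALTH_POOL, size=z)


@pytest.mark.parametrize("name", sorted(KERNELS))
class TestKernelIdentities:
    def test_sum_rule(self, name):
        """Exactly one agent dies: death probabilities sum to 1 for every
        wealth vector, to machine precision."""
        kernel = KERNELS[name]
        rng = np.random.default_rng(0)
        for w in random_wealth_vectors(1000, rng):
            assert abs(kernel.death_probs(w).sum() - 1.0) < 1e-12

    def test_equal_wealth_survival(self, name):
        kernel = KERNELS[name]
        for z in (2, 4, 6):
            for a in (0.0, 1.0, 3.7):
                w = np.full(z, a)
                assert kernel.survival(a, w[1:]) == pytest.approx(1 - 1 / z)

    def test_one_rich_identity(self, name):
        """With one wealth-w agent among equal-a competitors the two
        survival probabilities balance so deaths still sum to one."""
        kernel = KERNELS[name]
        rng = np.random.default_rng(1)
        for _ in range(100):
            z = int(rng.integers(2, 7))
            w, a = rng.choice(WEALTH_POOL, size=2)
            rest = np.full(z - 1, a)
            lhs = (1 - kernel.survival(w, rest)) + (z - 1) * (
                1 - kernel.survival(a, np.concatenate([[w], np.full(z - 2, a)]))
            )
            assert lhs == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_own_wealth(self, name):
        kernel = KERNELS[name]
        rng = np.random.default_rng(2)
        grid = np.linspace(0.0, 5.0, 11)
        for _ in range(50):
            z = int(rng.integers(2, 6))
            others = rng.choice(WEALTH_POOL, size=z - 1)
            vals = [kernel.survival(w, others) for w in grid]
            assert np.all(np.diff(vals) >= -1e-12)

    def test_batch_matches_scalar(self, name):
        kernel = KERNELS[name]
        rng = np.random.default_rng(3)
        W = rng.choice(WEALTH_POOL, size=(200, 4))
        batch = kernel.survival_batch(W)
        for row, kb in zip(W, batch):
            assert kernel.survival(row[0], row[1:]) == pytest.approx(kb)

    def test_symmetric_distributions_give_baseline(self, name):
        """Identical own and competitor wealth laws give P = 1 - 1/z for
        any exchangeable kernel (sum rule + symmetry)."""
        kernel = KERNELS[name]
        d = ZeroInflatedWealth(0.4, (0.5, 2.0), (0.25, 0.75))
        assert survival_probability_exact(kernel, d, d, 4) == pytest.approx(0.75)


class TestBox1Kernel:
    def test_scale_free_constant(self):
        """The sole rich agent among zeros survives with probability
        1 - 1/(2z) regardless of how rich it is."""
        k = KERNELS["box1"]
        for z in (2, 4, 8):
            lam = k.lambda_const(z)
            assert lam == pytest.approx(1 - 1 / (2 * z))
            for w in (0.1, 5.0, 1e6):
                assert k.survival(w, np.zeros(z - 1)) == pytest.approx(lam)

    def test_poorest_without_ties(self):
        k = KERNELS["box1"]
        z = 4
        assert k.survival(0.1, [1.0, 2.0, 3.0]) == pytest.approx(0.5 * (1 - 1 / z))

    def test_rich_atom_vs_penniless(self):
        own = ZeroInflatedWealth.atom(1.0, 5.0)
        comp = ZeroInflatedWealth.atom(0.0, 1.0)
        p = survival_probability_exact(KERNELS["box1"], own, comp, 4)
        assert p == pytest.approx(7 / 8)


class TestFirstOrder:
    def test_closed_form_special_cases(self):
        k = KERNELS["box1"]
        assert survival_probability_first_order(k, 0.3, 0.3, 4) == pytest.approx(0.75)
        # box1 at z=4: P = 3/4 + (eps - eps')/8
        assert survival_probability_first_order(k, 0.2, 0.1, 4) == pytest.approx(
            0.75 + 0.1 / 8
        )

    def test_lambda_floor_removes_wealth_benefit(self):
        """A kernel whose lone-rich survival equals the baseline 1-1/z
        gives eps-independent survival."""
        k = KERNELS["box1"]
        z = 4
        lam = 1 - 1 / z
        p = 1 - 1 / z + (0.7 - 0.1) * (lam - 1 + 1 / z)
        assert p == pytest.approx(1 - 1 / z)

    def test_non_scale_free_refused_with_bounds(self):
        k = KERNELS["smoothed_imitation"]
        with pytest.raises(NotScaleFreeError, match="P1"):
            survival_probability_first_order(k, 0.1, 0.0, 4)
        p1, p2 = survival_probability_bounds(0.1, 0.0, 4)
        assert p1 == pytest.approx(0.75)
        assert p2 == pytest.approx(0.75 + 0.1 / 4)

    @pytest.mark.parametrize(
        "name", ["box1", "imitate_if_better", "replicator", "ranked"]
    )
    def test_error_scales_quadratically(self, name):
        """The discrepancy between exact enumeration and the first-order
        form falls as eps^2: fitted log-log slope >= 2."""
        kernel = KERNELS[name]
        eps_list = np.array([1e-1, 1e-2, 1e-3])
        errs = []
        for eps in eps_list:
            own = ZeroInflatedWealth(eps, (1.0, 3.0), (0.5, 0.5))
            comp = ZeroInflatedWealth(eps / 3, (2.0, 0.5), (0.6, 0.4))
            ex = survival_probability_exact(kernel, own, comp, 4)
            fo = survival_probability_first_order(kernel, eps, eps / 3, 4)
            errs.append(abs(ex - fo))
        errs = np.array(errs)
        assert np.all(errs > 0)
        slope = np.polyfit(np.log(eps_list), np.log(errs), 1)[0]
        assert slope >= 2.0 - 1e-6

    def test_first_order_independent_of_payoff_magnitude(self):
        """Two strategies with equal zero-avoidance probability but very
        different pay-off sizes have survival rates equal to O(eps^2) —
        income does not matter, risk does."""
        k = KERNELS["box1"]
        eps, eps_c = 1e-3, 5e-4
        comp = ZeroInflatedWealth.atom(eps_c, 1.0)
        small = ZeroInflatedWealth.atom(eps, 0.01)
        large = ZeroInflatedWealth.atom(eps, 100.0)
        p_small = survival_probability_exact(k, small, comp, 4)
        p_large = survival_probability_exact(k, large, comp, 4)
        assert abs(p_small - p_large) < 5 * eps * eps_c


class TestExactVsMonteCarlo:
    def test_agreement_within_3_sigma(self):
        kernel = KERNELS["box1"]
        own = ZeroInflatedWealth(0.2, (1.0, 4.0), (0.5, 0.5))
        comp = ZeroInflatedWealth(0.1, (2.0,), (1.0,))
        exact = survival_probability_exact(kernel, own, comp, 4)
        mc, sem = survival_probability_mc(
            kernel, own, comp, 4, n_draws=1_000_000,
            rng=np.random.default_rng(11),
        )
        assert abs(mc - exact) < 3 * sem

    def test_bounds_hold_to_first_order(self):
        """P(s) lies within the model-free band [P1, P2] up to O(eps^2)."""
        rng = np.random.default_rng(4)
        eps, eps_c = 0.02, 0.005
        p1, p2 = survival_probability_bounds(eps, eps_c, 4)
        for name, kernel in KERNELS.items():
            if name == "linear":  # survival not confined to [0,1] off-balance
                continue
            own = ZeroInflatedWealth(eps, (1.0, 2.0), (0.5, 0.5))
            comp = ZeroInflatedWealth.atom(eps_c, 1.5)
            p = survival_probability_exact(kernel, own, comp, 4)
            assert p1 - 5 * eps**2 <= p <= p2 + 5 * eps**2, name

    def test_enumeration_cap_and_z_validation(self):
        k = KERNELS["box1"]
        big = ZeroInflatedWealth(0.5, tuple(range(1, 300)), (1 / 299,) * 299)
        with pytest.raises(ValueError, match="survival_probability_mc"):
            survival_probability_exact(k, big, big, 4)
        with pytest.raises(ValueError):
            survival_probability_exact(k, big, big, 1)


class TestInterfaceCounts:
    def test_homogeneous_dominant_triangle_scores_eight(self):
        s = Strategy(0.6, 0.2)
        assert interface_success_counts(s, [s] * 4) == 8

    def test_homogeneous_self_rejecting_scores_zero(self):
        s = Strategy(0.2, 0.6)
        assert interface_success_counts(s, [s] * 4) == 0

    def test_count_flat_within_open_triangle(self):
        """In a locally similar population the count does not depend on
        the offer: the fitness landscape is flat inside the triangle."""
        counts = {
            interface_success_counts(Strategy(p, 0.2), [Strategy(p, 0.2)] * 4)
            for p in (0.25, 0.5, 0.7, 0.95)
        }
        assert counts == {8}

    def test_mixed_interface_cases(self):
        grey = Strategy(0.2, 0.6)      # self-rejecting
        fair = Strategy(0.7, 0.3)      # dominant triangle
        # grey focal among 4 fair neighbours: as proposer always rejected
        # (0.2 < 0.3); as responder accepts 0.7 >= 0.6 -> 4 successes.
        assert interface_success_counts(grey, [fair] * 4) == 4
        # fair focal among greys: proposals accepted (0.7 >= 0.6);
        # responder games fail (0.2 < 0.3) -> 4.
        assert interface_success_counts(fair, [grey] * 4) == 4

    def test_boundary_payoffs_do_not_count(self):
        # p = 1 proposer keeps nothing; p = 0 responder receives nothing
        all_in = Strategy(1.0, 0.0)
        assert interface_success_counts(all_in, [all_in] * 4) == 4
        stingy = Strategy(0.0, 0.0)
        assert interface_success_counts(stingy, [stingy] * 4) == 4


class TestWellMixedGenerous:
    def test_mean_offer_is_three_quarters(self):
        assert well_mixed_generous_mean() == 0.75

    @pytest.mark.parametrize(
        "p, expected", [(0.5, 1.0), (0.9, 1.0), (0.2, 0.4), (0.0, 0.0)]
    )
    def test_acceptance_probability(self, p, expected):
        assert generous_acceptance_probability(p) == pytest.approx(expected)


def test_make_kernel_validation():
    with pytest.raises(ValueError):
        make_kernel("nope")
    with pytest.raises(ValueError):
        make_kernel("smoothed_imitation")  # alpha required
    k = make_kernel("smoothed_imitation", alpha=0.5)
    assert not k.scale_free and k.alpha == 0.5
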