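"""Exchange kernels, ladders, and sweep bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import titramem as tm
from titramem.exchange import (
    DUAL_FORCE_RULE,
    LadderReplica,
    build_window_ladder,
    constant_k_rule,
    exchange_sweep,
    extend_ph_ladder,
    harmonic_bias,
    harmonic_force,
    metropolis_accept,
    phre_delta,
    reus_delta,
)
from titramem.units import LN10, ThermoContext

THERMO = ThermoContext(300.0)


class TestHarmonicBias:
    def test_zero_at_reference(self):
        w = tm.Window("w", 0.7, 1000.0)
        assert harmonic_bias(0.7, w) == 0.0

    @pytest.mark.parametrize("k,expected", [(1000.0, 5.0), (500.0, 2.5)])
    def test_printed_force_constants(self, k, expected):
        # 0.1 nm displacement under the standard force constants
        w = tm.Window("w", 0.0, k)
        assert harmonic_bias(0.1, w) == pytest.approx(expected)

    def test_force_is_negative_gradient(self):
        w = tm.Window("w", 0.2, 300.0)
        assert harmonic_force(0.5, w) == pytest.approx(-300.0 * 0.3)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            tm.Window("w", 0.0, 0.0)


class TestReusDelta:
    def test_identical_configurations(self):
        m = tm.Window("m", 0.0, 1000.0)
        n = tm.Window("n", 0.2, 1000.0)
        assert reus_delta(0.1, 0.1, m, n, THERMO) == pytest.approx(0.0)

    def test_same_window_is_zero(self):
        m = tm.Window("m", 0.0, 1000.0)
        assert reus_delta(0.05, 0.15, m, m, THERMO) == pytest.approx(0.0)

    def test_hand_evaluated_example(self):
        # k=1000, refs 0 / 0.2 nm, xi_i=0.05, xi_j=0.15 at 300 K:
        # energy difference 20 kJ/mol -> Delta = 20/(0.0083145*300)
        m = tm.Window("m", 0.0, 1000.0)
        n = tm.Window("n", 0.2, 1000.0)
        delta = reus_delta(0.05, 0.15, m, n, THERMO)
        assert delta == pytest.approx(20.0 / (0.0083145 * 300.0), rel=1e-9)
        assert delta == pytest.approx(8.018, abs=2e-3)
        assert np.exp(-delta) == pytest.approx(3.3e-4, rel=0.01)

    @given(
        st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1),
        st.floats(10, 2000), st.floats(10, 2000),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_under_configuration_swap(self, xi_i, xi_j, rm, rn, km, kn):
        # the post-swap state has the configurations exchanged between
        # the same windows, and its Delta is the exact negative
        m = tm.Window("m", rm, km)
        n = tm.Window("n", rn, kn)
        assert reus_delta(xi_i, xi_j, m, n, THERMO) == pytest.approx(
            -reus_delta(xi_j, xi_i, m, n, THERMO), abs=1e-9
        )


class TestPhreDelta:
    def test_equal_proton_counts(self):
        assert phre_delta(1, 1, 4.0, 5.0) == 0.0

    def test_protonated_to_lower_ph_favorable(self):
        # replica j at pH 5 is protonated; the swap carries that
        # configuration down to pH 4, which is favorable
        delta = phre_delta(0, 1, 4.0, 5.0)
        assert delta == pytest.approx(-LN10)
        assert metropolis_accept(delta, np.random.default_rng(0)).accepted
        # the reverse move (protonated up to pH 5) is accepted with
        # probability 10^-1
        assert np.exp(-phre_delta(1, 0, 4.0, 5.0)) == pytest.approx(0.1)

    def test_antisymmetric_under_configuration_swap(self):
        assert phre_delta(1, 0, 4.0, 5.0) == pytest.approx(-phre_delta(0, 1, 4.0, 5.0))

    def test_detailed_balance_exact_flux(self):
        # two replicas at pH a < b with Henderson-Hasselbalch stationary
        # state probabilities: pi(x) w(x->y) must equal pi(y) w(y->x) for
        # the label swap on every discrete state pair
        pka = 5.0
        ph_a, ph_b = 4.5, 5.5

        def pi(n, ph):  # P(proton count n | ph)
            f_prot = 1.0 / (1.0 + 10.0 ** (ph - pka))
            return f_prot if n == 1 else 1.0 - f_prot

        for na in (0, 1):
            for nb in (0, 1):
                d = phre_delta(na, nb, ph_a, ph_b)
                w_fwd = min(1.0, np.exp(-d))
                w_rev = min(1.0, np.exp(d))
                lhs = pi(na, ph_a) * pi(nb, ph_b) * w_fwd
                rhs = pi(na, ph_b) * pi(nb, ph_a) * w_rev
                assert lhs == pytest.approx(rhs, rel=1e-12)


class TestMetropolis:
    def test_nonpositive_delta_always_accepted(self, rng):
        for delta in (-5.0, 0.0):
            assert all(metropolis_accept(delta, rng).accepted for _ in range(100))

    def test_empirical_acceptance_rate(self, rng):
        n = 100_000
        acc = sum(metropolis_accept(2.0, rng).accepted for _ in range(n))
        p = np.exp(-2.0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(acc / n - p) < 3 * se

    def test_decision_records_draw(self, rng):
        d = metropolis_accept(1.0, rng, pair=("a", "b"))
        assert 0.0 <= d.uniform_draw < 1.0
        assert d.accepted == (d.uniform_draw < np.exp(-1.0))


def _ladder_replicas(n, mode):
    reps = []
    for i in range(n):
        reps.append(
            LadderReplica(
                replica_id=f"r{i}",
                z=0.1 * i,
                proton_count=i % 2,
                pH=float(4 + i),
                window=tm.Window(f"w{i}", 0.1 * i, 500.0),
            )
        )
    return reps


class TestExchangeSweep:
    def test_even_parity_pairs_disjoint_adjacent(self, rng):
        reps = _ladder_replicas(4, "phre")
        decisions = exchange_sweep(reps, "even", "phre", rng)
        assert [d.pair for d in decisions] == [("r0", "r1"), ("r2", "r3")]
        decisions = exchange_sweep(_ladder_replicas(4, "phre"), "odd", "phre", rng)
        assert [d.pair for d in decisions] == [("r1", "r2")]

    def test_all_nonpositive_delta_swaps_everything(self, rng):
        # identical windows: Delta = 0 for every pair, all swaps accepted
        reps = _ladder_replicas(4, "reus")
        shared = tm.Window("shared", 0.0, 100.0)
        for r in reps:
            r.window = shared
        decisions = exchange_sweep(reps, "even", "reus", rng, thermo=THERMO)
        assert all(d.accepted for d in decisions)

    def test_fewer_than_two_replicas(self, rng):
        assert exchange_sweep(_ladder_replicas(1, "phre"), "even", "phre", rng) == []

    def test_ladder_multiset_invariance(self, rng):
        reps = _ladder_replicas(5, "phre")
        before = sorted(r.pH for r in reps)
        for i in range(50):
            exchange_sweep(reps, "even" if i % 2 == 0 else "odd", "phre", rng)
        assert sorted(r.pH for r in reps) == before
        assert sorted(r.replica_id for r in reps) == [f"r{i}" for i in range(5)]

    def test_ladder_order_maintained(self, rng):
        reps = _ladder_replicas(5, "phre")
        for i in range(20):
            exchange_sweep(reps, "even" if i % 2 == 0 else "odd", "phre", rng)
        phs = [r.pH for r in reps]
        assert phs == sorted(phs)


class TestWindowLadder:
    def test_printed_two_angstrom_ladder(self):
        ladder = build_window_ladder(20.0, -12.0, 2.0, constant_k_rule(1000.0))
        assert len(ladder) == 17
        assert ladder[0].xi_ref == pytest.approx(2.0)  # +20 A in nm
        assert ladder[-1].xi_ref == pytest.approx(-1.2)

    def test_one_angstrom_variant(self):
        ladder = build_window_ladder(12.0, -10.0, 1.0, constant_k_rule(1000.0))
        assert len(ladder) == 23

    def test_dual_force_rule(self):
        ladder = build_window_ladder(20.0, -12.0, 2.0, DUAL_FORCE_RULE)
        ks = {round(w.xi_ref * 10): w.k for w in ladder}
        for xi in (20, 18, 16, 14, 12, 10, 8):
            assert ks[xi] == 500.0
        for xi in (6, 4, 2, 0, -2, -4, -6, -8, -10, -12):
            assert ks[xi] == 1000.0

    def test_nondividing_spacing_rejected(self):
        with pytest.raises(ValueError, match="does not divide"):
            build_window_ladder(20.0, -12.0, 3.0, constant_k_rule(1000.0))

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            build_window_ladder(5.0, 5.0, 1.0, constant_k_rule(1000.0))


class TestExtendPhLadder:
    def test_acid_extends_high(self):
        assert extend_ph_ladder([3, 4, 5, 6], "acid") == [3, 4, 5, 6, 7, 8]

    def test_base_extends_low(self):
        assert extend_ph_ladder([8, 9, 10, 11], "base") == [6, 7, 8, 9, 10, 11]

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            extend_ph_ladder([7.0], "acid")

    def test_non_uniform_rejected(self):
        with pytest.raises(ValueError, match="uniformly"):
            extend_ph_ladder([3, 4, 6], "acid")


def brute_force_reus_acceptance(model, pH, win_a, win_b, n, rng):
    """Independent two-sampler estimate of the mean Eq-2 acceptance:
    draw xi from each window's biased density, average min(1, e^-Delta)."""
    grid = np.linspace(-1.4, 2.3, 4001)
    pa = model.analytic_biased_density(pH, grid, win_a)
    pb = model.analytic_biased_density(pH, grid, win_b)
    xi_a = rng.choice(grid, size=n, p=pa / pa.sum())
    xi_b = rng.choice(grid, size=n, p=pb / pb.sum())
    beta = model.thermo.beta
    delta = beta * (
        win_a.bias_energy(xi_b) - win_a.bias_energy(xi_a)
        - win_b.bias_energy(xi_b) + win_b.bias_energy(xi_a)
    )
    acc = np.minimum(1.0, np.exp(-delta))
    return float(acc.mean()), float(acc.std(ddof=1) / np.sqrt(n))


def test_acceptance_rate_increases_as_k_decreases():
    # softer umbrellas overlap more: mean acceptance must rise
    # monotonically over k in {1000, 500, 250} at fixed 2 A spacing
    m = tm.flat_model(confined=False)
    rng = np.random.default_rng(3)
    rates = []
    for k in (1000.0, 500.0, 250.0):
        wa = tm.Window("a", 0.0, k)
        wb = tm.Window("b", 0.2, k)
        rate, _ = brute_force_reus_acceptance(m, 5.0, wa, wb, 40_000, rng)
        rates.append(rate)
    assert rates[0] < rates[1] < rates[2]
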