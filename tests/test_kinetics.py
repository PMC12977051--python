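"""Persistence/exchange times, conditional activity, matrix assembly,
replica pooling and eigendomains, checked against hand computations,
a Monte-Carlo forward-recurrence oracle, analytic renewal limits, and
an independent eigensolver (power iteration)."""

import bisect

import numpy as np
import pytest

import condact as c
from condact.kinetics import waiting_intervals


def mc_persistence_oracle(record, n_samples=100_000, seed=0):
    """Definitional oracle: average forward recurrence time over uniformly
    random start times, with the next-transition search done by bisect
    (independent of the vectorized implementation)."""
    rng = np.random.default_rng(seed)
    times = list(record.times)
    total = 0.0
    for t in rng.uniform(0.0, record.tau, size=n_samples):
        i = bisect.bisect_right(times, t)
        nxt = times[i] if i < len(times) else record.tau
        total += nxt - t
    return total / n_samples


class TestPersistenceTime:
    def test_toy_record_hand_value(self, toy_record):
        # intervals (1, 2, 4, 0): (1 + 4 + 16 + 0) / (2 * 7) = 1.5
        assert c.persistence_time(toy_record) == pytest.approx(1.5)

    def test_toy_record_against_monte_carlo_oracle(self, toy_record):
        mc = mc_persistence_oracle(toy_record)
        assert c.persistence_time(toy_record) == pytest.approx(mc, rel=0.01)

    def test_periodic_clock_is_half_period(self):
        period, n = 2.5, 400
        rec = c.TransitionRecord(c.ResidueKey("A", 1, "VAL"),
                                 period * np.arange(1, n + 1), tau=period * n)
        assert c.persistence_time(rec) == pytest.approx(period / 2)

    def test_exponential_renewal_approaches_mean(self):
        mean = 3.0
        spec = c.RenewalSpec(("exponential", mean), tau=50_000.0, seed=11)
        rec = c.generate_renewal(spec)
        # tau_p -> <W^2> / (2<W>) = mean for the exponential law
        se = mean / np.sqrt(rec.n)
        assert abs(c.persistence_time(rec) - mean) < 3 * se

    def test_renewal_persistence_matches_monte_carlo_oracle(self):
        spec = c.RenewalSpec(("exponential", 5.0), tau=2000.0, seed=4)
        rec = c.generate_renewal(spec)
        mc = mc_persistence_oracle(rec)
        assert c.persistence_time(rec) == pytest.approx(mc, rel=0.01)

    def test_intervals_partition_tau(self, toy_record):
        assert waiting_intervals(toy_record).sum() == pytest.approx(7.0)

    def test_empty_record_flagged_missing(self):
        rec = c.TransitionRecord(c.ResidueKey("A", 1, "VAL"), [], tau=10.0)
        assert np.isnan(c.persistence_time(rec))


class TestExchangeTime:
    def test_toy_self_exchange_hand_value(self, toy_record):
        # i=1: W(X,3) * W(Y at 1) = 4 * 2; i=2: W(X,7) * W(Y at 3) = 0 * 4
        assert c.exchange_time(toy_record, toy_record) == pytest.approx(8 / 7)

    def test_single_term_sum_with_two_transitions(self, toy_record):
        y = c.TransitionRecord(c.ResidueKey("A", 2, "SER"), [2.0, 5.0], tau=7.0)
        # W(X, 5) = 7 - 5 = 2 (next X transition at 7); W(Y at 2) = 3
        assert c.exchange_time(toy_record, y) == pytest.approx(2 * 3 / 7)

    def test_fewer_than_two_y_transitions_undefined(self, toy_record):
        y = c.TransitionRecord(c.ResidueKey("A", 2, "SER"), [2.0], tau=7.0)
        assert np.isnan(c.exchange_time(toy_record, y))

    def test_mismatched_tau_rejected(self, toy_record):
        y = c.TransitionRecord(c.ResidueKey("A", 2, "SER"), [1.0, 2.0], tau=9.0)
        with pytest.raises(ValueError):
            c.exchange_time(toy_record, y)

    def test_independent_poisson_exchange_approaches_persistence(self):
        x = c.generate_renewal(c.RenewalSpec(("exponential", 1.0), 10_000.0, seed=1))
        y = c.generate_renewal(c.RenewalSpec(("exponential", 1.0), 10_000.0, seed=2))
        assert c.exchange_time(x, y) == pytest.approx(c.persistence_time(x),
                                                      rel=0.1)


class TestConditionalActivity:
    def test_toy_memory_hand_value(self, toy_record):
        expected = np.log(21 / 16)  # -ln((8/7) / 1.5)
        assert c.conditional_activity(toy_record, toy_record) == pytest.approx(expected)

    def test_equal_times_give_zero(self, toy_record):
        # A = -ln(1) when exchange equals persistence: engineered via identity
        tp = c.persistence_time(toy_record)
        assert -np.log(tp / tp) == 0.0

    def test_periodic_clock_memory_is_minus_ln2(self):
        rec = c.generate_renewal(c.RenewalSpec(("fixed", 1.0), 10_000.0))
        a = c.conditional_activity(rec, rec)
        assert a == pytest.approx(-np.log(2), abs=0.01)
        # exact finite-N value: the two boundary-censored terms give
        # tau_xx = (N-2)/N * c and tau_p = c/2 exactly
        n = rec.n
        assert a == pytest.approx(-np.log(2 * (n - 2) / n), abs=1e-12)

    def test_poisson_memory_is_zero_within_noise(self):
        values = []
        for seed in range(60):
            rec = c.generate_renewal(
                c.RenewalSpec(("exponential", 1.0), 5000.0, seed=seed))
            values.append(c.conditional_activity(rec, rec))
        se = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(np.mean(values)) < 3 * se

    def test_bursty_clock_has_positive_memory(self):
        spec = c.RenewalSpec(("mixture", 1.0, 40.0, 0.8), 20_000.0, seed=5)
        rec = c.generate_renewal(spec)
        # analytic large-N limit: ln(E[W^2] / (2 E[W]^2))
        ew = 0.8 * 1.0 + 0.2 * 40.0
        ew2 = 0.8 * 2 * 1.0 + 0.2 * 2 * 40.0 ** 2
        expected = np.log(ew2 / (2 * ew ** 2))
        assert c.conditional_activity(rec, rec) == pytest.approx(expected,
                                                                 abs=0.25)

    def test_fully_censored_exchange_flagged_missing(self):
        x = c.TransitionRecord(c.ResidueKey("A", 1, "VAL"), [10.0], tau=10.0)
        y = c.TransitionRecord(c.ResidueKey("A", 2, "SER"), [9.0, 10.0], tau=10.0)
        # X's only transition precedes every W evaluation point -> censored 0
        assert np.isnan(c.conditional_activity(x, y))


class TestDirectionality:
    def test_master_slave_asymmetry_recovered(self):
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            master = c.RenewalSpec(("exponential", 1.0), 1000.0, seed=seed)
            base = c.RenewalSpec(("exponential", 10.0), 1000.0,
                                 key=c.ResidueKey("SYN", 2, "SYN"))
            coup = c.CouplingSpec(trigger_probability=1.0, lag=("fixed", 0.01))
            m, s = c.generate_coupled_pair(master, coup, slave_baseline=base)
            a_sm = c.conditional_activity(s, m)
            a_ms = c.conditional_activity(m, s)
            if a_sm > a_ms:
                wins += 1
        assert wins >= 0.95 * n_seeds

    def test_slave_master_activity_strongly_positive(self):
        master = c.RenewalSpec(("exponential", 1.0), 1000.0, seed=7)
        base = c.RenewalSpec(("exponential", 10.0), 1000.0,
                             key=c.ResidueKey("SYN", 2, "SYN"))
        coup = c.CouplingSpec(trigger_probability=1.0, lag=("fixed", 0.01))
        m, s = c.generate_coupled_pair(master, coup, slave_baseline=base)
        assert c.conditional_activity(s, m) > 2.0


class TestActivityMatrix:
    def test_orientation_row_is_affected_residue(self, toy_record):
        y = c.TransitionRecord(c.ResidueKey("A", 2, "SER"),
                               [2.0, 5.0, 6.0], tau=7.0)
        mat = c.activity_matrix([toy_record, y])
        assert mat.values[0, 1] == pytest.approx(
            c.conditional_activity(toy_record, y))
        assert mat.values[1, 0] == pytest.approx(
            c.conditional_activity(y, toy_record))

    def test_diagonal_is_memory(self, toy_record):
        mat = c.activity_matrix([toy_record, toy_record.with_times([2.0, 4.0, 6.0])])
        assert mat.memory[0] == pytest.approx(np.log(21 / 16))

    def test_independent_pair_near_zero(self):
        x = c.generate_renewal(c.RenewalSpec(("exponential", 1.0), 10_000.0, seed=21))
        y = c.generate_renewal(c.RenewalSpec(
            ("exponential", 1.0), 10_000.0, seed=22,
            key=c.ResidueKey("SYN", 2, "SYN")))
        mat = c.activity_matrix([x, y])
        assert abs(mat.values[0, 1]) < 0.1
        assert abs(mat.values[1, 0]) < 0.1

    def test_symmetrization_removes_asymmetry_exactly(self, toy_record):
        y = c.TransitionRecord(c.ResidueKey("A", 2, "SER"),
                               [2.0, 5.0, 6.0], tau=7.0)
        s = c.activity_matrix([toy_record, y]).symmetrized()
        assert np.allclose(s, s.T)


class TestPoolReplicas:
    def _mat(self, values, keys, replica):
        return c.ActivityMatrix(residue_index=keys,
                                values=np.asarray(values, dtype=float),
                                persistence_times=np.ones(len(keys)),
                                replica_id=replica)

    def test_two_replicas_mean_and_sem(self):
        keys = [c.ResidueKey("A", 1, "VAL"), c.ResidueKey("A", 2, "SER")]
        m1 = self._mat([[1.0, 1.0], [1.0, 1.0]], keys, 0)
        m2 = self._mat([[3.0, 3.0], [3.0, 3.0]], keys, 1)
        pooled = c.pool_replicas([m1, m2])
        assert np.allclose(pooled.values, 2.0)
        assert np.allclose(pooled.sem, 1.0)

    def test_single_replica_mean_no_sem(self):
        keys = [c.ResidueKey("A", 1, "VAL"), c.ResidueKey("A", 2, "SER")]
        pooled = c.pool_replicas([self._mat([[1.0, 2.0], [3.0, 4.0]], keys, 0)])
        assert np.allclose(pooled.values, [[1.0, 2.0], [3.0, 4.0]])
        assert np.all(np.isnan(pooled.sem))

    def test_entry_missing_in_one_replica_averages_the_rest(self):
        keys = [c.ResidueKey("A", 1, "VAL"), c.ResidueKey("A", 2, "SER")]
        m1 = self._mat([[1.0, np.nan], [1.0, 1.0]], keys, 0)
        m2 = self._mat([[3.0, 2.0], [3.0, 3.0]], keys, 1)
        m3 = self._mat([[5.0, 4.0], [5.0, 5.0]], keys, 2)
        pooled = c.pool_replicas([m1, m2, m3])
        assert pooled.values[0, 1] == pytest.approx(3.0)  # mean of 2, 4

    def test_disjoint_residue_universes_union(self):
        k1 = [c.ResidueKey("A", 1, "VAL")]
        k2 = [c.ResidueKey("A", 2, "SER")]
        pooled = c.pool_replicas([self._mat([[0.5]], k1, 0),
                                  self._mat([[0.7]], k2, 1)])
        assert len(pooled.residue_index) == 2
        assert np.isnan(pooled.values[0, 1])


def power_iteration_oracle(s, iters=2000):
    v = np.ones(s.shape[0]) / np.sqrt(s.shape[0])
    shift = np.abs(s).sum() + 1.0  # make the top eigenvalue dominant & positive
    m = s + shift * np.eye(s.shape[0])
    for _ in range(iters):
        v = m @ v
        v /= np.linalg.norm(v)
    return float(v @ s @ v), v


class TestEigendomains:
    def test_two_by_two_closed_form(self):
        keys = [c.ResidueKey("A", 1, "VAL"), c.ResidueKey("A", 2, "SER")]
        mat = c.ActivityMatrix(keys, np.array([[0.0, 1.0], [1.0, 0.0]]),
                               np.ones(2))
        dom = c.eigendomains(mat)
        assert dom.eigenvalue == pytest.approx(1.0)
        assert np.allclose(np.abs(dom.components), 1 / np.sqrt(2))

    def test_block_matrix_against_power_iteration_oracle(self):
        rng = np.random.default_rng(0)
        block1 = 2.0 + rng.random((3, 3));  block1 = (block1 + block1.T) / 2
        block2 = 0.2 * rng.random((3, 3));  block2 = (block2 + block2.T) / 2
        s = np.zeros((6, 6))
        s[:3, :3], s[3:, 3:] = block1, block2
        keys = [c.ResidueKey("A", i + 1, "VAL") for i in range(6)]
        dom = c.eigendomains(c.ActivityMatrix(keys, s, np.ones(6)))
        ev, vec = power_iteration_oracle(s)
        assert dom.eigenvalue == pytest.approx(ev, rel=1e-8)
        assert np.allclose(np.abs(dom.components), np.abs(vec), atol=1e-6)
        # mass concentrates on the stronger block
        assert dom.scores[:3].sum() > 5 * dom.scores[3:].sum()

    def test_symmetric_input_unchanged_by_symmetrization(self):
        s = np.array([[0.0, 0.3], [0.3, 0.1]])
        keys = [c.ResidueKey("A", 1, "VAL"), c.ResidueKey("A", 2, "SER")]
        mat = c.ActivityMatrix(keys, s, np.ones(2))
        assert np.allclose(mat.symmetrized(), s)

    def test_all_zero_matrix_degenerate(self):
        keys = [c.ResidueKey("A", 1, "VAL"), c.ResidueKey("A", 2, "SER")]
        mat = c.ActivityMatrix(keys, np.zeros((2, 2)), np.ones(2))
        with pytest.raises(ValueError):
            c.eigendomains(mat)

    def test_sign_convention_largest_component_positive(self):
        keys = [c.ResidueKey("A", i + 1, "VAL") for i in range(3)]
        s = np.array([[2.0, 0.5, 0.0], [0.5, 1.0, 0.1], [0.0, 0.1, 0.2]])
        dom = c.eigendomains(c.ActivityMatrix(keys, s, np.ones(3)))
        assert dom.components[np.argmax(np.abs(dom.components))] > 0
        assert np.linalg.norm(dom.components) == pytest.approx(1.0)
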