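import math

import numpy as np
import pytest
from scipy import stats as sps

from hybcoal.network import (
    RejectedNetwork,
    advance_time,
    apply_hybrid_speciation,
    apply_introgression,
    apply_speciation,
    draw_event,
    enforce_reticulation_count,
    simulate_conditioned_network,
    simulate_network,
)
from hybcoal.params import (
    ContributionDistribution,
    Epoch,
    EpochSchedule,
    HaltingConfig,
    RateSet,
)


def constant_schedule(**kw):
    return EpochSchedule.constant(RateSet(**kw), kw.pop("success_kind", "step"))


class TestDistanceUpdates:
    def test_advance_doubles_elapsed_time(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        advance_time(D, 0.5)
        assert np.array_equal(D, [[0.0, 2.0], [2.0, 0.0]])

    def test_advance_zero_is_noop_and_diagonal_stays_zero(self, rng):
        D = rng.random((4, 4))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        before = D.copy()
        advance_time(D, 0.0)
        assert np.array_equal(D, before)
        advance_time(D, 3.7)
        assert np.all(np.diag(D) == 0)

    def test_speciation_copies_parent_row(self):
        D = np.array([[0.0, 4.0], [4.0, 0.0]])
        out = apply_speciation(D, 0)
        assert out[2, 0] == 0.0  # child at zero distance from parent
        assert out[2, 1] == 4.0  # and at the parent's distance from others

    def test_hybrid_weighted_average(self):
        D = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        out = apply_hybrid_speciation(D, 0, 1, gamma=0.5)
        assert out[3, 0] == pytest.approx(1.0)  # (1-gamma)*d(a,b)
        assert out[3, 1] == pytest.approx(1.0)  # gamma*d(a,b)
        assert out[3, 2] == pytest.approx(4.0)  # average of equal values

    def test_hybrid_gamma_one_copies_parent(self):
        D = np.array([[0.0, 2.0, 3.0], [2.0, 0.0, 5.0], [3.0, 5.0, 0.0]])
        out = apply_hybrid_speciation(D, 0, 1, gamma=1.0)
        assert out[3, 2] == pytest.approx(D[0, 2])
        assert out[3, 0] == pytest.approx(0.0)

    def test_introgression_row_average(self):
        D = np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 1.0], [6.0, 1.0, 0.0]])
        out = apply_introgression(D.copy(), donor=0, recipient=1, gamma=0.1)
        assert out[1, 0] == pytest.approx(0.9 * 2.0)
        assert out[1, 2] == pytest.approx(0.9 * 1.0 + 0.1 * 6.0)
        assert np.allclose(out, out.T)

    def test_introgression_gamma_one_copies_donor(self):
        D = np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 1.0], [6.0, 1.0, 0.0]])
        out = apply_introgression(D.copy(), donor=0, recipient=1, gamma=1.0)
        assert out[1, 0] == 0.0
        assert out[1, 2] == pytest.approx(6.0)

    def test_identical_parents_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            apply_hybrid_speciation(D, 1, 1, 0.5)
        with pytest.raises(ValueError):
            apply_introgression(D, 2, 2, 0.5)


class TestEventDraws:
    def test_only_speciation_when_no_reticulation_rates(self, rng):
        sched = constant_schedule(lambda_S=1.0)
        kinds = {draw_event(0.0, 3, sched, rng).kind for _ in range(200)}
        assert kinds == {"speciation"}

    def test_waiting_time_is_exponential(self, rng):
        # N=2, lambda_S=1 -> total rate 2; KS against Exp(2)
        sched = constant_schedule(lambda_S=1.0)
        draws = np.array([draw_event(0.0, 2, sched, rng).delta_t for _ in range(10000)])
        assert abs(draws.mean() - 0.5) < 3 * 0.5 / math.sqrt(len(draws))
        assert sps.kstest(draws, "expon", args=(0, 0.5)).pvalue > 0.01

    def test_epoch_boundary_restart_invisible_when_rates_match(self, rng):
        one = constant_schedule(lambda_S=1.0)
        r = RateSet(lambda_S=1.0)
        two = EpochSchedule([Epoch(0, 0.3, r), Epoch(0.3, math.inf, r)])
        d1 = np.array([draw_event(0.0, 2, one, rng).delta_t for _ in range(8000)])
        d2 = np.array([draw_event(0.0, 2, two, rng).delta_t for _ in range(8000)])
        assert sps.ks_2samp(d1, d2).pvalue > 0.01

    def test_event_type_frequencies(self, rng):
        sched = constant_schedule(lambda_S=1.0, lambda_H=0.1, lambda_I=0.1)
        n = 100000
        kinds = [draw_event(0.0, 3, sched, rng).kind for _ in range(n)]
        pH = 0.6 / 4.2
        freq = sum(k == "hybrid_attempt" for k in kinds) / n
        assert abs(freq - pH) < 3 * math.sqrt(pH * (1 - pH) / n)


class TestSimulateNetwork:
    def test_pure_yule_species_halt(self, rng):
        sched = constant_schedule(lambda_S=1.0)
        net = simulate_network(sched, HaltingConfig(max_species=10), rng)
        assert net.n_species == 10
        assert net.n_reticulations == 0
        assert net.halt_reason == "max_species"
        # binary tree: n-1 speciation events (including the founding one)
        assert sum(e.kind == "speciation" for e in net.events) == 9
        assert net.end_time > max(e.time for e in net.events)

    def test_depth_halt_sets_exact_depth(self, rng):
        sched = constant_schedule(lambda_S=1.0)
        net = simulate_network(sched, HaltingConfig(max_depth=1.5), rng)
        assert net.halt_reason == "max_depth"
        assert net.end_time == 1.5

    def test_sister_distance_is_twice_divergence_time(self, rng):
        # with no reticulations, d(parent, child) = 2 * (end - divergence time)
        sched = constant_schedule(lambda_S=1.0)
        net = simulate_network(sched, HaltingConfig(max_depth=2.0), rng,
                               keep_distances=True)
        D = net.distances
        for ev in net.events[1:]:
            assert D[ev.a, ev.child] == pytest.approx(2 * (net.end_time - ev.time))

    def test_step_success_with_huge_threshold_always_succeeds(self, rng):
        sched = constant_schedule(lambda_S=1.0, lambda_H=0.3, T=1e12)
        net = simulate_network(sched, HaltingConfig(max_species=12), rng)
        # every reticulation attempt succeeded: hybrids + speciations = 11 events
        assert net.n_species == 12
        assert len(net.hybrid_events) > 0

    def test_distance_matrix_invariants_maintained(self, rng):
        sched = EpochSchedule.constant(
            RateSet(lambda_S=1.0, lambda_H=0.2, lambda_I=0.2, T=1.0), "linear"
        )
        # in-loop assertions active:
        simulate_network(sched, HaltingConfig(max_species=15), rng, _check_invariants=True)

    def test_reticulation_halt(self, rng):
        sched = constant_schedule(lambda_S=0.01, lambda_H=1.0, T=1e12)
        net = simulate_network(sched, HaltingConfig(max_species=100, max_reticulations=3), rng)
        assert net.halt_reason in ("max_reticulations", "max_species")
        assert net.n_reticulations <= 3


class TestReticulationConditioning:
    def test_reject_below_minimum(self, rng):
        sched = constant_schedule(lambda_S=1.0)
        net = simulate_network(sched, HaltingConfig(max_species=6), rng)
        with pytest.raises(RejectedNetwork):
            enforce_reticulation_count(net, 2, 2, rng)

    def test_reduce_to_exact_count(self, rng):
        sched = constant_schedule(lambda_S=1.0, lambda_H=0.3, T=1e12)
        halt = HaltingConfig(max_species=10, min_reticulations=2, reduce_to_reticulations=2)
        for _ in range(5):
            net = simulate_conditioned_network(sched, halt, rng)
            assert net.n_reticulations == 2
            assert net.n_species == 10

    def test_no_reduction_when_unlimited(self, rng):
        sched = constant_schedule(lambda_S=1.0, lambda_H=0.3, T=1e12)
        net = simulate_network(sched, HaltingConfig(max_species=10), rng)
        out = enforce_reticulation_count(net, 0, math.inf, rng)
        assert out.n_reticulations == net.n_reticulations

    def test_eliminated_hybrid_becomes_divergence(self, rng):
        sched = constant_schedule(lambda_S=1.0, lambda_H=0.5, T=1e12)
        halt = HaltingConfig(max_species=10, min_reticulations=0, reduce_to_reticulations=0)
        net = simulate_conditioned_network(sched, halt, rng)
        assert net.n_reticulations == 0
        assert net.n_species == 10  # species created by hybrids persist
        assert sum(e.kind == "speciation" for e in net.events) == 9
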