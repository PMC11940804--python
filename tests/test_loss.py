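"""Packet-loss injection models: exactness, conservation, chain statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spikeloss import (CongestionParams, CountMatrix, DistributedParams,
                       GEParams, SpikeEvents, burst_loss, calibrate_bandwidth,
                       congestion_loss, events_from_counts, full_loss,
                       ge_params_from, loss_rate_series, single_loss)


def make_counts(rng, n_bins=30, n_units=6, lam=2.0):
    return CountMatrix(rng.poisson(lam, size=(n_bins, n_units)), 0.128)


class TestCongestion:
    def test_no_exceedance_is_identity(self, small_counts, rng):
        ev = events_from_counts(small_counts, rng)
        Z = int(small_counts.counts.sum(axis=1).max())
        out, rep = congestion_loss(small_counts, ev, CongestionParams(Z))
        np.testing.assert_array_equal(out.counts, small_counts.counts)
        assert rep.overall_rate == 0.0

    def test_zero_bandwidth_drops_everything(self, small_counts, rng):
        ev = events_from_counts(small_counts, rng)
        out, rep = congestion_loss(small_counts, ev, CongestionParams(0))
        assert out.total_spikes == 0
        assert rep.overall_rate == 1.0

    def test_latest_spike_dropped_in_overfull_bin(self):
        # 1 bin, units with counts (3, 2), Z=4: brute-force ordering of the
        # 5 timestamps says exactly the latest one must go.
        times0 = np.array([0.010, 0.040, 0.100])
        times1 = np.array([0.020, 0.090])
        A = CountMatrix(np.array([[3, 2]]), 0.128)
        ev = SpikeEvents([times0, times1])
        out, rep = congestion_loss(A, ev, CongestionParams(4))
        all_spikes = sorted([(t, 0) for t in times0] + [(t, 1) for t in times1])
        latest_unit = all_spikes[-1][1]
        expected = np.array([[3, 2]])
        expected[0, latest_unit] -= 1
        np.testing.assert_array_equal(out.counts, expected)
        assert out.counts.sum() == 4

    def test_row_sum_law_on_random_fixtures(self, rng):
        A = make_counts(rng, n_bins=40, n_units=8, lam=3.0)
        ev = events_from_counts(A, rng)
        X = A.counts.sum(axis=1)
        for Z in (0, 3, 10, 17, 25):
            out, rep = congestion_loss(A, ev, CongestionParams(Z))
            np.testing.assert_array_equal(out.counts.sum(axis=1),
                                          np.minimum(X, Z))
            assert np.all(out.counts <= A.counts)

    def test_mismatched_events_rejected(self, small_counts, rng):
        other = make_counts(rng, n_bins=small_counts.n_bins,
                            n_units=small_counts.n_units)
        ev = events_from_counts(other, rng)
        with pytest.raises(ValueError, match="inconsistent"):
            congestion_loss(small_counts, ev, CongestionParams(5))


class TestFullLoss:
    def test_exact_row_count(self, rng):
        A = make_counts(rng, n_bins=100)
        out, rep = full_loss(A, DistributedParams(0.02, seed=0))
        assert rep.mask.sum() == 2
        assert np.all(out.counts[rep.mask] == 0)
        np.testing.assert_array_equal(out.counts[~rep.mask],
                                      A.counts[~rep.mask])

    def test_p_zero_identity(self, small_counts):
        out, rep = full_loss(small_counts, DistributedParams(0.0, seed=0))
        np.testing.assert_array_equal(out.counts, small_counts.counts)
        assert rep.overall_rate == 0.0

    def test_p_one_zeroes_matrix(self, small_counts):
        out, rep = full_loss(small_counts, DistributedParams(1.0, seed=0))
        assert out.total_spikes == 0
        assert rep.mask.all()

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            DistributedParams(1.5)


class TestSingleLoss:
    def test_two_decrements_land_in_valid_outcome_set(self):
        # exhaustive oracle: every reachable outcome of 2 unit decrements
        A0 = np.array([[2, 0], [1, 3]])
        valid = set()
        cells = [(i, j) for i in range(2) for j in range(2)]
        for first, second in itertools.product(cells, repeat=2):
            M = A0.copy()
            if M[first] > 0:
                M[first] -= 1
            else:
                continue
            if M[second] > 0:
                M[second] -= 1
            else:
                continue
            valid.add(tuple(M.ravel()))
        A = CountMatrix(A0, 0.128)
        for seed in range(30):
            dp = DistributedParams(0.5, mode="paper_literal", seed=seed)
            out, rep = single_loss(A, dp)  # L = round(p*N*C) = 2
            assert out.counts.sum() == 4
            assert np.all(out.counts >= 0)
            assert tuple(out.counts.ravel()) in valid

    def test_p_zero_identity(self, small_counts):
        out, _ = single_loss(small_counts, DistributedParams(0.0, seed=1))
        np.testing.assert_array_equal(out.counts, small_counts.counts)

    def test_spike_fraction_removes_exact_half(self, rng):
        counts = rng.multinomial(100, np.ones(25) / 25).reshape(5, 5)
        A = CountMatrix(counts, 0.128)
        out, rep = single_loss(A, DistributedParams(
            0.5, mode="spike_fraction", seed=3))
        assert out.total_spikes == 50
        assert np.all(out.counts >= 0)
        assert rep.overall_rate == 0.5

    def test_shortfall_error_names_deficit(self):
        A = CountMatrix(np.array([[1, 0], [0, 1]]), 0.128)
        with pytest.raises(ValueError, match="shortfall"):
            single_loss(A, DistributedParams(1.0, mode="paper_literal", seed=0))


class TestBurstLoss:
    def test_absorbing_good_state_never_loses(self, small_counts):
        out, rep = burst_loss(small_counts, GEParams(0.0, 0.3, seed=0))
        np.testing.assert_array_equal(out.counts, small_counts.counts)
        assert not rep.mask.any()

    def test_deterministic_alternating_chain(self, rng):
        A = make_counts(rng, n_bins=10, lam=5.0)
        out, rep = burst_loss(A, GEParams(1.0, 1.0, seed=0))
        # starting Good: G,B,G,B,... so odd bins are zeroed
        np.testing.assert_array_equal(rep.mask, np.arange(10) % 2 == 1)
        assert np.all(out.counts[1::2] == 0)
        np.testing.assert_array_equal(out.counts[0::2], A.counts[0::2])

    def test_stationary_fraction_and_burst_length(self, rng):
        # closed form: Bad fraction -> p/(p+q); mean Bad dwell -> 1/q
        p, q, n = 0.01, 0.49, 100_000
        A = CountMatrix(rng.poisson(1.0, size=(n, 2)), 0.128)
        _, rep = burst_loss(A, GEParams(p, q, seed=2024))
        frac = rep.mask.mean()
        target = p / (p + q)
        assert abs(frac - target) < 3 * np.sqrt(target * (1 - target) / n)
        # burst (run) lengths of the Bad state
        m = np.r_[0, rep.mask.view(np.int8), 0]
        starts = np.flatnonzero(np.diff(m) == 1)
        ends = np.flatnonzero(np.diff(m) == -1)
        runs = ends - starts
        se = np.sqrt((1 - q) / q**2 / runs.size)
        assert abs(runs.mean() - 1 / q) < 3 * se

    def test_partial_severity_rounds_per_bin(self, rng):
        A = make_counts(rng, n_bins=50, lam=4.0)
        _, rep = burst_loss(A, GEParams(0.5, 0.5, loss_fraction_in_bad=0.5,
                                        seed=5))
        hit = rep.mask & (rep.original_per_bin > 0)
        expect = np.floor(0.5 * rep.original_per_bin[hit] + 0.5)
        np.testing.assert_array_equal(rep.lost_per_bin[hit], expect)


class TestGEParamsFrom:
    def test_half_loss_single_bin_bursts(self):
        ge = ge_params_from(0.5, 1.0)
        assert ge.p_gb == pytest.approx(1.0)
        assert ge.q_bg == pytest.approx(1.0)

    def test_two_percent_two_bin_bursts(self):
        ge = ge_params_from(0.02, 2.0)
        assert ge.q_bg == pytest.approx(0.5)
        assert ge.p_gb == pytest.approx(0.02 * 0.5 / 0.98)

    @given(p_loss=st.floats(0.001, 0.45), mbl=st.floats(1.0, 20.0))
    def test_round_trip_stationary_loss(self, p_loss, mbl):
        ge = ge_params_from(p_loss, mbl)
        assert ge.stationary_loss == pytest.approx(p_loss, rel=1e-12)

    def test_degenerate_loss_rejected(self):
        for bad in (0.0, 1.0):
            with pytest.raises(ValueError):
                ge_params_from(bad, 2.0)


class TestCalibrateBandwidth:
    def test_target_zero_gives_lossless_bandwidth(self, small_counts, rng):
        cp = calibrate_bandwidth(small_counts, 0.0)
        ev = events_from_counts(small_counts, rng)
        _, rep = congestion_loss(small_counts, ev, cp)
        assert rep.overall_rate == 0.0
        assert cp.bandwidth_Z == small_counts.counts.sum(axis=1).max()

    def test_matches_brute_force_scan(self, rng):
        A = make_counts(rng, n_bins=60, n_units=5, lam=3.0)
        X = A.counts.sum(axis=1)
        total = X.sum()
        for target in (0.01, 0.05, 0.2, 0.5):
            cp = calibrate_bandwidth(A, target)
            rates = np.array([np.maximum(X - z, 0).sum() / total
                              for z in range(int(X.max()) + 1)])
            best = np.abs(rates - target).min()
            achieved = np.maximum(X - cp.bandwidth_Z, 0).sum() / total
            assert abs(achieved - target) == pytest.approx(best, abs=1e-12)

    def test_rate_monotone_in_bandwidth(self, rng):
        A = make_counts(rng, n_bins=40, lam=2.0)
        X = A.counts.sum(axis=1)
        total = X.sum()
        rates = [np.maximum(X - z, 0).sum() / total
                 for z in range(int(X.max()) + 2)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_invalid_target_rejected(self, small_counts):
        with pytest.raises(ValueError):
            calibrate_bandwidth(small_counts, 1.0)


class TestAccountingInvariants:
    @pytest.mark.parametrize("model", ["congestion", "full", "single", "burst"])
    def test_conservation(self, model, rng):
        A = make_counts(rng, n_bins=50, n_units=7, lam=2.5)
        if model == "congestion":
            ev = events_from_counts(A, rng)
            out, rep = congestion_loss(A, ev, CongestionParams(10))
        elif model == "full":
            out, rep = full_loss(A, DistributedParams(0.1, seed=1))
        elif model == "single":
            out, rep = single_loss(A, DistributedParams(0.05, seed=1))
        else:
            out, rep = burst_loss(A, GEParams(0.1, 0.4, seed=1))
        assert rep.original_per_bin.sum() - rep.lost_per_bin.sum() == out.total_spikes
        np.testing.assert_array_equal(rep.original_per_bin, A.counts.sum(axis=1))
        assert np.all(out.counts >= 0)

    @pytest.mark.parametrize("model", ["full", "single", "burst"])
    def test_seeded_reproducibility(self, model, rng):
        A = make_counts(rng)
        def run():
            if model == "full":
                return full_loss(A, DistributedParams(0.1, seed=7))
            if model == "single":
                return single_loss(A, DistributedParams(0.05, seed=7))
            return burst_loss(A, GEParams(0.2, 0.5, seed=7))
        out1, _ = run()
        out2, _ = run()
        np.testing.assert_array_equal(out1.counts, out2.counts)


class TestLossRateSeries:
    def test_per_bin_rates(self):
        from spikeloss.loss import LossReport
        rep = LossReport(lost_per_bin=[0, 5], original_per_bin=[10, 10],
                         mask=[False, True], model_name="full")
        np.testing.assert_allclose(loss_rate_series(rep), [0.0, 0.5])

    def test_all_lost_is_all_ones(self):
        from spikeloss.loss import LossReport
        rep = LossReport([3, 4], [3, 4], [True, True], "burst")
        np.testing.assert_allclose(loss_rate_series(rep), 1.0)

    def test_weighted_mean_matches_overall_rate(self, rng):
        A = make_counts(rng)
        _, rep = full_loss(A, DistributedParams(0.2, seed=0))
        r = loss_rate_series(rep)
        w = rep.original_per_bin
        assert np.average(r[w > 0], weights=w[w > 0]) == pytest.approx(
            rep.overall_rate)

    def test_empty_bins_report_zero(self):
        from spikeloss.loss import LossReport
        rep = LossReport([0, 0], [0, 5], [False, False], "single")
        np.testing.assert_allclose(loss_rate_series(rep), [0.0, 0.0])
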