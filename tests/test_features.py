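import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spiketypes.features import (
    Autocorrelogram,
    InsufficientDataError,
    autocorrelogram,
    autocorrelogram_metric,
    burst_stats,
    dip_statistic,
    dip_test,
    intraburst_frequency,
    isi_histogram,
    isi_peak,
    log_isi_drop,
    refractory_period,
)
from spiketypes.synth import DEFAULT_PHENOTYPES, bursting_train, poisson_train


class TestIsiHistogram:
    def test_log_convention_anchors_ln_ms(self):
        """Identical 20 ms ISIs land in the single bin containing ln(20)=3.0."""
        h = isi_histogram(np.full(100, 0.020), scale="log")
        occupied = h.centers[h.counts > 0]
        assert occupied.size == 1
        assert abs(occupied[0] - 3.0) <= 0.05  # ln(20 ms) = 2.9957

    def test_linear_binning(self):
        """ISIs {1, 1, 3} ms in 0.2 ms bins: 2 counts in the bin starting at
        1.0 ms and 1 count in the bin starting at 3.0 ms."""
        h = isi_histogram(np.array([0.001, 0.001, 0.003]), scale="linear")
        assert h.counts[np.isclose(h.edges[:-1], 1.0)].sum() == 2
        assert h.counts[np.isclose(h.edges[:-1], 3.0)].sum() == 1
        assert h.counts.sum() == 3

    @given(st.lists(st.floats(min_value=1e-4, max_value=1.0), min_size=0, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_counts_sum_to_n_intervals(self, isis):
        for scale in ("linear", "log"):
            h = isi_histogram(np.array(isis), scale=scale)
            assert h.counts.sum() == h.n_intervals == len(isis)


class TestIsiPeak:
    def test_bursting_peak_at_intraburst(self):
        t = bursting_train(
            8.0, DEFAULT_PHENOTYPES["Bu1"], (0.0, 200.0), np.random.default_rng(0)
        )
        peak = isi_peak(isi_histogram(np.diff(t), "log"))
        assert 1.1 <= peak <= 1.5  # ms

    def test_poisson_peak_at_mean_isi(self):
        t = poisson_train(50.0, (0.0, 400.0), np.random.default_rng(1), refractory=0.0)
        peak = isi_peak(isi_histogram(np.diff(t), "log"))
        assert 16.0 <= peak <= 25.0  # analytic mode of ln-ISI = ln(20 ms)

    def test_needs_50_intervals(self):
        with pytest.raises(InsufficientDataError):
            isi_peak(isi_histogram(np.full(40, 0.002), "log"))

    def test_truncated_below_80ms(self):
        """A dominant peak beyond 80 ms is ignored in favor of the sub-80 ms
        structure (the truncation avoids the repetition-period peak)."""
        isis = np.concatenate([np.full(500, 0.700), np.full(100, 0.002)])
        peak = isi_peak(isi_histogram(isis, "log"))
        assert peak < 10.0


class TestRefractoryPeriod:
    def test_first_bin_exceeding_1_200th_of_peak(self):
        """Counts {0,0,5,100}: threshold 0.5, first qualifying bin at 0.4 ms."""
        isis = np.concatenate([np.full(5, 0.0005), np.full(100, 0.0007)])
        assert refractory_period(isi_histogram(isis, "linear")) == pytest.approx(4e-4)

    def test_uniform_counts_give_first_bin(self):
        isis = np.array([0.0001, 0.0003, 0.0005, 0.0007])
        assert refractory_period(isi_histogram(isis, "linear")) == pytest.approx(0.0)


class TestLogIsiDrop:
    def test_pure_short_peak_scores_one(self):
        assert log_isi_drop(np.full(100, 0.002)) == pytest.approx(1.0, abs=0.05)

    def test_pure_reference_band_scores_minus_one(self):
        assert log_isi_drop(np.full(100, 0.012)) == pytest.approx(-1.0, abs=0.05)

    def test_minimum_intervals(self):
        with pytest.raises(InsufficientDataError):
            log_isi_drop(np.full(49, 0.002))

    def test_bu1_prestim_band(self):
        """Bu1 spontaneous activity scores in the reported [0.7, 1.0] band."""
        ph = DEFAULT_PHENOTYPES["Bu1"]
        rng = np.random.default_rng(3)
        scores = []
        for _ in range(5):
            isis = []
            for _ in range(300):
                seg = bursting_train(ph.spontaneous_rate, ph, (0.0, 0.2), rng)
                if seg.size >= 2:
                    isis.append(np.diff(seg))
            scores.append(log_isi_drop(np.concatenate(isis)))
        assert 0.7 <= np.mean(scores) <= 1.0


class TestAutocorrelogram:
    def test_single_pair(self):
        ac = autocorrelogram([np.array([0.0, 0.0011])])
        centers = 0.5 * (ac.edges[:-1] + ac.edges[1:])
        hit = ac.counts[(centers > 1.0) & (centers < 1.2)]
        assert hit.sum() == 1 and ac.counts.sum() == 1

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(4)
        segs = [np.sort(rng.uniform(0, 0.7, rng.integers(5, 60))) for _ in range(6)]
        ac = autocorrelogram(segs, lag_max=0.080)
        brute = np.zeros_like(ac.counts)
        for seg in segs:
            for i in range(len(seg)):
                for j in range(len(seg)):
                    if j <= i:
                        continue
                    lag = (seg[j] - seg[i]) * 1000.0
                    if lag < 80.0:
                        brute[int(lag // 0.2)] += 1
        np.testing.assert_array_equal(ac.counts, brute)

    def test_poisson_flat_expectation(self):
        """Homogeneous Poisson: expected pair count per bin = r^2 T dt."""
        rng = np.random.default_rng(5)
        t = poisson_train(40.0, (0.0, 400.0), rng, refractory=0.0)
        ac = autocorrelogram([t], lag_max=0.080)
        expected = 40.0**2 * 400.0 * 0.0002
        centers = 0.5 * (ac.edges[:-1] + ac.edges[1:])
        observed = ac.counts[centers > 1.0].mean()  # skip the few refractory-free short bins
        assert abs(observed - expected) < 5 * np.sqrt(expected)

    def test_prestim_and_full_autocorrelogram_share_peak(self, bench_session):
        """Bursting is a unit property: the prestimulus-only autocorrelogram
        peaks in the same bin as the full one."""
        from spiketypes.session import slice_epoch

        bu = next(u for u in bench_session if u.truth_type == "Bu1")
        full = autocorrelogram([tr.times for tr in bu.trains], lag_max=0.010)
        pre = autocorrelogram(
            [slice_epoch(tr, (-0.2, 0.0)).times for tr in bu.trains], lag_max=0.010
        )
        assert np.argmax(full.counts) == np.argmax(pre.counts)


class TestAutocorrelogramMetric:
    def _make(self, short, long):
        edges = np.arange(0.0, 80.2, 0.2)
        counts = np.zeros(edges.size - 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts[centers < 8.0] = short
        counts[(centers >= 35.0) & (centers < 80.0)] = long
        return Autocorrelogram(edges=edges, counts=counts)

    @pytest.mark.parametrize("short,long,expected", [(5, 0, 1.0), (3, 3, 0.0), (0, 7, -1.0)])
    def test_extremes(self, short, long, expected):
        assert autocorrelogram_metric(self._make(short, long)) == pytest.approx(expected)

    def test_invariant_to_rescaling(self):
        ac = self._make(5, 2)
        scaled = Autocorrelogram(edges=ac.edges, counts=ac.counts * 17.0)
        assert autocorrelogram_metric(scaled) == pytest.approx(autocorrelogram_metric(ac))

    def test_empty_undefined(self):
        assert autocorrelogram_metric(self._make(0, 0)) is None


class TestIntraburstFrequency:
    @pytest.mark.parametrize(
        "center_ms,expected_hz", [(1.3, 769.2), (1.9, 526.3), (9.9, 101.0)]
    )
    def test_inverse_of_linear_peak(self, center_ms, expected_hz):
        isis = np.full(60, center_ms / 1000.0)
        got = intraburst_frequency(isi_histogram(isis, "linear"))
        assert got == pytest.approx(expected_hz, rel=0.02)

    def test_500hz_boundary_from_2ms(self):
        """A 2.0 ms intraburst interval sits exactly at the Bu1/Bu2 boundary
        (bin center 1.9 ms gives 526 Hz; 2.1 ms gives 476 Hz)."""
        low = intraburst_frequency(isi_histogram(np.full(60, 0.0021), "linear"))
        assert low < 500.0


class TestBurstStats:
    def test_burst_runs_counted_in_spikes(self):
        """ISIs {1,1,50,1,1,1} ms with peak 1 ms: bursts of 3 and 4 spikes."""
        s = burst_stats(np.array([1, 1, 50, 1, 1, 1]) / 1000.0, 1.0)
        assert s["max_burst_len"] == 4
        assert s["mean_burst_len"] == pytest.approx(3.5)

    def test_periodic_train_regularity_zero(self):
        s = burst_stats(np.full(100, 0.010), 10.0)
        assert s["regularity"] == pytest.approx(0.0, abs=1e-12)

    def test_poisson_pct_normalized_near_one(self):
        t = poisson_train(30.0, (0.0, 600.0), np.random.default_rng(6), refractory=0.0)
        iv = np.diff(t)
        s = burst_stats(iv, 1000.0 / 30.0)
        assert 0.9 <= s["pct_normalized"] <= 1.1


class TestDipTest:
    def test_two_point_sample_exact(self):
        assert dip_statistic([0.0, 1.0]) == pytest.approx(0.25)

    def test_floor_at_1_over_2n(self):
        x = np.linspace(0, 1, 100)
        assert dip_statistic(x) == pytest.approx(1 / 200, abs=1e-9)

    def test_monotone_in_cluster_separation(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 250)
        dips = [
            dip_statistic(np.concatenate([base, rng.normal(sep, 1, 250)]))
            for sep in (0.0, 3.0, 6.0)
        ]
        assert dips[0] < dips[1] < dips[2]

    def test_uniform_null_not_rejected(self):
        u = np.random.default_rng(8).uniform(0, 1, 500)
        res = dip_test(u, n_boot=500, rng_seed=1)
        assert res["p"] > 0.3

    def test_bimodal_rejected(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 1, 250), rng.normal(6, 1, 250)])
        res = dip_test(x, n_boot=500, rng_seed=1)
        assert res["p"] < 0.01

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            dip_test(np.arange(5))
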