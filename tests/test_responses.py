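import numpy as np
import pytest

from spiketypes.responses import (
    RAYLEIGH_CRIT,
    adaptation_index,
    onset_latency,
    period_histogram,
    response_window,
    responsive_by_psth,
    responsive_by_rate,
    sam_summary,
    smoothed_psth,
    vector_strength,
    vs_profile,
)
from spiketypes.session import SpikeTrain, StimulusDescriptor, UnitRecording


def make_unit(trains_times, duration=0.2, kind="tone", mod_rate=None, n_prestim_spikes=0,
              prestim_rate_trains=None):
    stim = StimulusDescriptor(
        stimulus_id="S1", kind=kind, duration=duration, mod_rate=mod_rate
    )
    span = (-0.2, duration + 0.3)
    trains = [
        SpikeTrain(np.asarray(t, float), span, "S1", rep)
        for rep, t in enumerate(trains_times)
    ]
    return UnitRecording("u", trains, {"S1": stim})


class TestSmoothedPsth:
    def test_single_spike_integrates_to_one(self):
        p = smoothed_psth([np.array([0.1])], (0.0, 0.3))
        integral = p.rate.sum() * 0.001
        assert integral == pytest.approx(1.0, rel=1e-3)

    def test_empty_trains_all_zero(self):
        p = smoothed_psth([np.array([])], (0.0, 0.3))
        assert np.all(p.rate == 0.0)

    def test_constant_rate_flat(self):
        rng = np.random.default_rng(0)
        trains = [np.sort(rng.uniform(0, 1.0, 100)) for _ in range(30)]
        p = smoothed_psth(trains, (0.0, 1.0))
        mid = p.rate[50:-50]
        assert mid.std() / mid.mean() < 0.15

    def test_edge_spike_count_conserved_within_tolerance(self):
        """Spikes >= 3 sigma from the window edges conserve integrated count
        to better than 0.1%."""
        p = smoothed_psth([np.array([0.05, 0.15, 0.25])], (0.0, 0.3))
        assert p.rate.sum() * 0.001 == pytest.approx(3.0, rel=1e-3)


class TestResponseWindow:
    @pytest.mark.parametrize(
        "kind,duration,expected",
        [
            ("tone", 0.2, (0.010, 0.250)),
            ("vocalization", 1.0, (0.010, 1.150)),
            ("tone", 0.0125, (0.010, 0.0625)),
        ],
    )
    def test_window_rule(self, kind, duration, expected):
        stim = StimulusDescriptor(stimulus_id="s", kind=kind, duration=duration)
        assert response_window(stim) == pytest.approx(expected)


class TestResponsiveByRate:
    def test_threshold_arithmetic(self):
        """Prestim mean 5, var 4, T_pre = T_resp via duration scaling,
        n_reps = 10: threshold = 5 + 3*sqrt(4*(0.2/0.24)/10) ~ 6.73; a
        driven rate of 20 clears it, a driven rate equal to the mean does
        not."""
        rng = np.random.default_rng(0)
        # build prestim segments with controlled mean/var via spike counts
        counts = rng.poisson(1.0, 200)  # 5 spk/s in 0.2 s
        span = (-0.2, 0.5)
        stim = StimulusDescriptor(stimulus_id="S1", kind="tone", duration=0.2)
        trains = []
        for rep, c in enumerate(counts):
            pre = np.sort(rng.uniform(-0.2, -1e-6, c))
            if pre.size > 1:
                pre = pre[np.concatenate(([True], np.diff(pre) > 0))]
            driven = np.sort(rng.uniform(0.01, 0.25, 5)) if rep < 10 else np.array([])
            t = np.unique(np.concatenate([pre, driven]))
            trains.append(SpikeTrain(t, span, "S1", rep))
        unit = UnitRecording("u", trains[:10], {"S1": stim})
        # driven 5 spikes / 0.24 s ~ 20.8 spk/s >> threshold
        assert responsive_by_rate(unit, "S1")

    def test_driven_equal_to_mean_not_responsive(self):
        rng = np.random.default_rng(1)
        stim = StimulusDescriptor(stimulus_id="S1", kind="tone", duration=0.2)
        span = (-0.2, 0.5)
        trains = []
        for rep in range(20):
            t = np.sort(rng.uniform(-0.2, 0.5, 7))
            t = t[np.concatenate(([True], np.diff(t) > 0))] if t.size > 1 else t
            trains.append(SpikeTrain(t, span, "S1", rep))
        unit = UnitRecording("u", trains, {"S1": stim})
        assert not responsive_by_rate(unit, "S1")


class TestResponsiveByPsth:
    def test_exact_poisson_tail(self):
        """lambda = 1 expected count per 5 ms bin: a max bin of 12 has tail
        probability ~8e-10 (explicit series), far below the Bonferroni
        threshold of 0.01/100 bins."""
        from math import exp, factorial

        from scipy.stats import poisson

        p = poisson.sf(11, 1.0)
        tail = 1.0 - sum(exp(-1.0) / factorial(k) for k in range(12))
        assert p == pytest.approx(tail, rel=1e-6)
        assert p < 0.01 / 100

    def test_phase_locked_unit_detected_by_psth_not_rate(self, pattern_session):
        """A Bu1 unit can respond in instantaneous rate (max PSTH bin)
        without exceeding the overall-rate threshold for some stimulus."""
        found = False
        for u in pattern_session:
            if u.truth_type != "Bu1":
                continue
            for sid, st in u.stimuli.items():
                if st.kind != "vocalization":
                    continue
                if responsive_by_psth(u, sid) and not responsive_by_rate(u, sid):
                    found = True
                    break
            if found:
                break
        assert found


class TestAdaptationIndex:
    def _unit(self, early_times, late_times):
        trains = [np.concatenate([early_times, late_times])]
        return make_unit(trains)

    def test_arithmetic(self):
        # 30 early spikes vs 10 late -> (30-10)/(30+10) = 0.5
        early = np.linspace(0.02, 0.1, 30)
        late = np.linspace(0.12, 0.2, 10)
        u = self._unit(early, late)
        assert adaptation_index(u, "S1") == pytest.approx(0.5)

    def test_stationary_zero(self):
        early = np.linspace(0.02, 0.1, 20)
        late = np.linspace(0.12, 0.2, 20)
        assert adaptation_index(self._unit(early, late), "S1") == pytest.approx(0.0)

    def test_pure_onset_one(self):
        u = self._unit(np.linspace(0.02, 0.05, 8), np.array([]))
        assert adaptation_index(u, "S1") == pytest.approx(1.0)

    def test_antisymmetric_under_time_reversal(self):
        early = np.linspace(0.02, 0.1, 30)
        late = np.linspace(0.12, 0.2, 10)
        ai = adaptation_index(self._unit(early, late), "S1")
        # reverse within the offset-by-10ms response window [0.01, 0.21)
        rev_all = np.sort(0.22 - np.concatenate([early, late]))
        ai_rev = adaptation_index(self._unit(rev_all, np.array([])), "S1")
        assert ai_rev == pytest.approx(-ai)

    def test_silent_undefined(self):
        assert np.isnan(adaptation_index(self._unit(np.array([]), np.array([])), "S1"))


class TestVectorStrength:
    def test_perfect_locking(self):
        """100 spikes at one phase: VS = 1, Rayleigh = 200, significant."""
        u = make_unit([np.arange(10) * 0.5 + 0.26 for _ in range(10)],
                      duration=5.0, kind="SAM", mod_rate=2.0)
        prof = vs_profile(u)[0]
        assert prof["vs"] == pytest.approx(1.0, abs=1e-9)
        assert prof["rayleigh"] == pytest.approx(2 * prof["n_spikes"], rel=1e-9)
        assert prof["significant"]

    def test_rayleigh_exactly_critical_not_significant(self):
        """VS = 0.1 with N = 690 gives Rayleigh = 13.8 exactly; the strict
        inequality keeps it nonsignificant and VS_reported = 0."""
        from spiketypes.responses import rayleigh_significant

        n = 690
        vs = 0.1
        rayleigh = 2 * n * vs**2
        assert rayleigh == pytest.approx(RAYLEIGH_CRIT)
        assert not rayleigh_significant(rayleigh)
        assert rayleigh_significant(13.9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        ph = rng.uniform(0, 2 * np.pi, 500)
        shift = 1.234
        a = vector_strength(ph)
        b = vector_strength((ph + shift) % (2 * np.pi))
        assert a == pytest.approx(b, abs=1e-12)

    def test_uniform_null_rarely_significant(self):
        """P(2 N VS^2 > 13.8) ~ 0.001 under uniform phases."""
        rng = np.random.default_rng(1)
        n, trials = 200, 20000
        ph = rng.uniform(0, 2 * np.pi, (trials, n))
        c = np.cos(ph).sum(axis=1)
        s = np.sin(ph).sum(axis=1)
        vs2 = (c**2 + s**2) / n**2
        frac = np.mean(2 * n * vs2 > RAYLEIGH_CRIT)
        assert frac == pytest.approx(0.001, abs=0.0008)


class TestSamSummary:
    def _profile(self, entries):
        return [
            {
                "mod_rate": f,
                "stimulus_id": f"sam{f}",
                "n_spikes": 100,
                "vs": vs,
                "rayleigh": ray,
                "significant": ray > RAYLEIGH_CRIT,
                "vs_reported": vs if ray > RAYLEIGH_CRIT else 0.0,
            }
            for f, vs, ray in entries
        ]

    def test_single_significant_rate(self):
        prof = self._profile([(4.0, 0.02, 1.0), (16.0, 0.6, 72.0), (32.0, 0.03, 2.0)])
        s = sam_summary(prof)
        assert s["sync_4"] and s["sync_16"]
        assert s["tbmf"] is None  # needs >= 2 significant rates

    def test_fmax_interpolated_between_brackets(self):
        prof = self._profile([(16.0, 0.5, 50.0), (32.0, 0.15, 5.0)])
        s = sam_summary(prof)
        assert 16.0 < s["f_max"] < 32.0

    def test_fmax_at_highest_tested_rate(self):
        prof = self._profile([(256.0, 0.4, 32.0), (512.0, 0.4, 32.0)])
        assert sam_summary(prof)["f_max"] == 512.0

    def test_tbmf_unweighted_geometric_mean_when_equal_vs(self):
        prof = self._profile([(4.0, 0.5, 50.0), (8.0, 0.5, 50.0), (16.0, 0.01, 1.0)])
        s = sam_summary(prof)
        assert s["tbmf"] == pytest.approx(np.sqrt(32.0), rel=1e-6)  # sqrt(4*8)

    def test_unsynchronized_requires_rate_response(self):
        prof = self._profile([(4.0, 0.02, 1.0), (8.0, 0.02, 1.0)])
        assert sam_summary(prof, [True, False])["unsynchronized"]
        assert sam_summary(prof, [False, False])["excluded"]


class TestPeriodHistogram:
    def test_delta_at_single_phase(self):
        u = make_unit([np.arange(10) * 0.5 + 0.26 for _ in range(5)],
                      duration=5.0, kind="SAM", mod_rate=2.0)
        edges, dens = period_histogram(u, 2.0)
        assert np.sum(dens > 0) == 1
        assert dens.sum() * (edges[1] - edges[0]) == pytest.approx(1.0)

    def test_bursting_phenotype_peaks_before_crest(self, pattern_session):
        """Rising-slope-driven units concentrate spikes in the first
        half-cycle (the envelope crest is at phase pi)."""
        bu = next(u for u in pattern_session if u.truth_type == "Bu1")
        edges, dens = period_histogram(bu, 2.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mass_rising = dens[centers < np.pi].sum()
        assert mass_rising > 0.7 * dens.sum()


class TestOnsetLatency:
    def test_matches_generator_latency(self, bench_session):
        """Measured latency tracks the phenotype's driven-component latency
        (8 ms for the fast bursters) within the smoothing scale."""
        bu = next(u for u in bench_session if u.truth_type == "Bu1")
        lat = onset_latency(bu, [s for s, st in bu.stimuli.items() if st.kind == "tone"])
        assert lat is not None
        assert abs(lat - 0.008) < 0.008

    def test_unresponsive_unit_undefined(self):
        rng = np.random.default_rng(0)
        trains = [np.sort(rng.uniform(-0.2, 0.5, 3)) for _ in range(10)]
        u = make_unit(trains)
        assert onset_latency(u) is None

    def test_minimum_over_stimuli(self, bench_session):
        """The unit-level latency is the earliest across stimuli."""
        u = next(x for x in bench_session if x.truth_type == "FS")
        tone_ids = [s for s, st in u.stimuli.items() if st.kind == "tone"]
        per_stim = [onset_latency(u, [sid]) for sid in tone_ids]
        per_stim = [p for p in per_stim if p is not None]
        assert onset_latency(u, tone_ids) == pytest.approx(min(per_stim))
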