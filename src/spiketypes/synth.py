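"""Labeled synthetic benchmark sessions.

The generator emulates the statistical structure of four extracellular unit
phenotypes recorded in awake primate auditory cortex:

``RS``
    regular-spiking: broad waveform (t_TTP ~0.7 ms), low spontaneous rate,
    stimulus-selective sustained firing that follows the stimulus envelope,
    moderate spike-time jitter (a rate code).
``FS``
    fast-spiking: narrow waveform (~0.3 ms), high spontaneous and driven
    rates, weakly selective sustained firing close to a Poisson process.
``Bu1``
    high-frequency burster ("chattering-like"): sporadic 2-4 spike bursts at
    intraburst intervals < 2 ms, present in spontaneous activity, driven by
    the *rising slope* of the stimulus envelope, temporally precise, strongly
    adapting (onset-dominated).
``Bu2``
    lower-frequency burster: intraburst interval >= 2 ms, mixed
    slope/envelope drive, less precise.

Spiking is generated as an (in)homogeneous Poisson process by thinning with
an absolute dead time; bursting units use a two-stage process in which burst
*events* are a point process and each event expands into a short
fixed-interval spike group.  All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import SpikeTrain, StimulusDescriptor, UnitRecording

ABS_REFRACTORY = 0.0008  # s, absolute refractory applied within and between bursts

ENVELOPE_DT = 0.001  # s, envelope grid step

#: SAM modulation rates used throughout (Hz, octave spacing)
SAM_RATES = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0, 512.0)

#: duration series (s)
DURATIONS = (0.0125, 0.025, 0.05, 0.1, 0.2, 0.4)

#: linear onset ramp times for the ramp series (s)
RAMP_TIMES = (0.005, 0.01, 0.02, 0.04)


@dataclass(frozen=True)
class Envelope:
    """Stimulus amplitude envelope on a uniform 1 ms grid, amplitude in [0, 1]."""

    t: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.amplitude, float)
        t = np.asarray(self.t, float)
        if a.min() < -1e-9 or a.max() > 1 + 1e-9:
            raise ValueError("envelope amplitude must lie in [0, 1]")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "amplitude", a)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) + ENVELOPE_DT

    def rising_slope(self) -> np.ndarray:
        """Rectified time derivative of the envelope (1/s), >= 0."""
        d = np.gradient(self.amplitude, self.t)
        return np.clip(d, 0.0, None)

    def __call__(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, self.amplitude, left=0.0, right=0.0)


@dataclass(frozen=True)
class UnitPhenotype:
    """Generative parameters of one synthetic unit type."""

    type: str  # RS | FS | Bu1 | Bu2
    spontaneous_rate: float  # spk/s (event/s for bursting types)
    driven_rate: float  # spk/s (event/s for bursting types) at full drive
    adaptation_tau: float = 0.15  # s
    sustained_fraction: float = 0.4  # floor of the adaptation profile
    burst_prob: float = 0.0  # per-event probability of a multi-spike burst
    intraburst_interval: float = 0.0013  # s
    burst_length_dist: dict[int, float] = field(
        default_factory=lambda: {2: 0.55, 3: 0.35, 4: 0.10}
    )
    phase_lock_kappa: float = 1.0  # sharpening exponent on the rising slope
    slope_drive: float = 0.0  # 0 = envelope drive, 1 = pure rising-slope drive
    jitter_sd: float = 0.0  # s, per-spike (per-event) timing jitter
    trial_gain_sd: float = 0.35  # lognormal sigma of per-trial response gain
    latency: float = 0.015  # s, response latency of the driven component
    selectivity: float = 0.0  # 0 = uniform gains, 1 = strongly selective
    waveform_ttp: float = 0.0007  # s, trough-to-peak of the spike waveform
    waveform_noise: float = 0.025  # additive noise SD relative to trough depth

    def __post_init__(self):
        if self.spontaneous_rate < 0 or self.driven_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.burst_prob <= 1:
            raise ValueError("burst_prob must lie in [0, 1]")
        if self.burst_prob > 0 and self.intraburst_interval <= ABS_REFRACTORY:
            raise ValueError("intraburst interval must exceed the absolute refractory")
        if self.burst_length_dist and abs(sum(self.burst_length_dist.values()) - 1) > 1e-9:
            raise ValueError("burst_length_dist must sum to 1")


#: default phenotypes; rates are chosen so that each type satisfies its own
#: classification criteria (spontaneous <3 / >5 spk/s, waveform widths around
#: the 0.5 ms boundary, intraburst intervals straddling 2 ms).
DEFAULT_PHENOTYPES: dict[str, UnitPhenotype] = {
    "RS": UnitPhenotype(
        type="RS",
        spontaneous_rate=1.0,
        driven_rate=60.0,
        adaptation_tau=0.12,
        sustained_fraction=0.6,
        jitter_sd=0.010,
        latency=0.018,
        selectivity=1.0,
        waveform_ttp=0.0007,
    ),
    "FS": UnitPhenotype(
        type="FS",
        spontaneous_rate=12.0,
        driven_rate=55.0,
        adaptation_tau=0.15,
        sustained_fraction=0.85,
        jitter_sd=0.008,
        latency=0.012,
        selectivity=0.3,
        waveform_ttp=0.0003,
    ),
    "Bu1": UnitPhenotype(
        type="Bu1",
        spontaneous_rate=1.6,  # burst events/s
        driven_rate=130.0,  # burst events/s at full (edge) drive
        adaptation_tau=0.05,
        sustained_fraction=0.0,
        burst_prob=0.85,
        intraburst_interval=0.0013,
        phase_lock_kappa=2.0,
        slope_drive=1.0,
        jitter_sd=0.0012,
        latency=0.008,
        selectivity=0.5,
        waveform_ttp=0.00045,
    ),
    "Bu2": UnitPhenotype(
        type="Bu2",
        spontaneous_rate=1.6,
        driven_rate=32.0,
        adaptation_tau=0.1,
        sustained_fraction=0.3,
        burst_prob=0.85,
        intraburst_interval=0.0028,
        phase_lock_kappa=1.0,
        slope_drive=0.55,
        jitter_sd=0.004,
        latency=0.016,
        selectivity=0.5,
        waveform_ttp=0.00055,
    ),
}


# ---------------------------------------------------------------------------
# envelopes


def _grid(duration: float) -> np.ndarray:
    n = max(1, int(round(duration / ENVELOPE_DT)))
    return np.arange(n) * ENVELOPE_DT


def sam_envelope(mod_rate: float, duration: float) -> Envelope:
    """Sinusoidal amplitude modulation at 100% depth: 0.5*(1 - cos(2 pi f t))."""
    if mod_rate <= 0:
        raise ValueError("mod_rate must be > 0")
    t = _grid(duration)
    return Envelope(t=t, amplitude=0.5 * (1.0 - np.cos(2 * np.pi * mod_rate * t)))


def flat_envelope(duration: float, ramp_time: float = 0.005) -> Envelope:
    """Flat-topped envelope with a linear onset ramp."""
    if ramp_time > duration:
        raise ValueError("ramp_time cannot exceed the stimulus duration")
    t = _grid(duration)
    amp = np.minimum(t / ramp_time if ramp_time > 0 else np.ones_like(t), 1.0)
    return Envelope(t=t, amplitude=np.clip(amp, 0.0, 1.0))


def duration_and_ramp_envelopes(
    durations=DURATIONS, ramp_times=(0.005,)
) -> list[Envelope]:
    """Flat-topped envelopes for every (duration, ramp) combination."""
    out = []
    for d in durations:
        for r in ramp_times:
            out.append(flat_envelope(d, r))
    return out


def vocalization_envelope(
    n_events: int,
    duration: float,
    rng: np.random.Generator | int,
    trill: bool = False,
    attack: float = 0.004,
    decay: float = 0.06,
) -> Envelope:
    """Synthetic call-like envelope: randomly placed sharp-attack/slow-decay
    events, optionally carrying a ~30 Hz sub-modulation (trill-like).

    A stand-in for prerecorded vocalization tokens; deterministic given rng.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    t = _grid(duration)
    amp = np.zeros_like(t)
    # keep events away from the very end so each has room to decay
    onsets = np.sort(rng.uniform(0.01, max(0.011, duration - 2 * decay), n_events))
    heights = rng.uniform(0.5, 1.0, n_events)
    for t0, h in zip(onsets, heights):
        rel = t - t0
        ev = np.where(
            rel < 0,
            0.0,
            np.where(rel < attack, rel / attack, np.exp(-(rel - attack) / decay)),
        )
        amp = np.maximum(amp, h * ev)
    if trill:
        amp = amp * (0.5 * (1.0 - np.cos(2 * np.pi * 30.0 * t)))
    peak = amp.max()
    if peak > 0:
        amp = amp / peak
    return Envelope(t=t, amplitude=amp)


# ---------------------------------------------------------------------------
# point processes


def _rate_on_grid(rate, span: tuple[float, float]):
    """Return (t_grid, rate_grid) for a rate given as scalar, callable or Envelope."""
    t0, t1 = span
    tg = np.arange(t0, t1 + ENVELOPE_DT, ENVELOPE_DT)
    if np.isscalar(rate):
        return tg, np.full_like(tg, float(rate))
    if isinstance(rate, Envelope):
        return tg, rate(tg)
    return tg, np.asarray(rate(tg), dtype=float)


def _enforce_dead_time(times: np.ndarray, dead: float) -> np.ndarray:
    if times.size == 0:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= dead:
            keep.append(t)
    return np.asarray(keep)


def poisson_train(
    rate,
    span: tuple[float, float],
    rng: np.random.Generator | int,
    refractory: float = ABS_REFRACTORY,
    jitter_sd: float = 0.0,
) -> np.ndarray:
    """Spike times of an (in)homogeneous Poisson process with dead time.

    ``rate`` may be a scalar (spk/s), an :class:`Envelope` (interpreted as a
    rate profile in spk/s), or a callable ``t -> rate``.  Thinning is used
    for inhomogeneous rates; the candidate intensity is corrected by
    ``1 / (1 - rate * refractory)`` so that the realized mean rate matches
    the target despite the dead time.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    t0, t1 = span
    if np.isscalar(rate):
        # homogeneous: no thinning grid needed
        r = max(float(rate), 0.0)
        if refractory > 0:
            r = r / max(1.0 - r * refractory, 0.2)
        if r <= 0:
            return np.empty(0)
        n_cand = rng.poisson(r * (t1 - t0))
        times = np.sort(rng.uniform(t0, t1, n_cand))
    else:
        tg, rg = _rate_on_grid(rate, span)
        rg = np.clip(rg, 0.0, None)
        if refractory > 0:
            rg = rg / np.clip(1.0 - rg * refractory, 0.2, 1.0)
        rmax = float(rg.max(initial=0.0))
        if rmax <= 0:
            return np.empty(0)
        n_cand = rng.poisson(rmax * (t1 - t0))
        cand = np.sort(rng.uniform(t0, t1, n_cand))
        accept = rng.uniform(0, 1, n_cand) < np.interp(cand, tg, rg) / rmax
        times = cand[accept]
    if jitter_sd > 0:
        times = np.sort(times + rng.normal(0.0, jitter_sd, times.size))
        times = times[(times >= t0) & (times < t1)]
    if refractory > 0:
        times = _enforce_dead_time(times, refractory)
    return times


def bursting_train(
    event_rate,
    phenotype: UnitPhenotype,
    span: tuple[float, float],
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Two-stage bursting process: burst events are an (in)homogeneous point
    process; each event expands to ``k`` spikes at the phenotype's intraburst
    interval (with probability ``burst_prob``, else a single spike).

    The event process carries a dead time long enough that consecutive bursts
    do not interleave; spikes additionally respect the absolute refractory.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    max_len = max(phenotype.burst_length_dist) if phenotype.burst_length_dist else 1
    event_dead = phenotype.intraburst_interval * max_len + 0.002
    events = poisson_train(
        event_rate, span, rng, refractory=event_dead, jitter_sd=phenotype.jitter_sd
    )
    if events.size == 0:
        return events
    ks, ps = zip(*sorted(phenotype.burst_length_dist.items()))
    lengths = np.where(
        rng.uniform(0, 1, events.size) < phenotype.burst_prob,
        rng.choice(ks, size=events.size, p=ps),
        1,
    )
    spikes = []
    for t_ev, k in zip(events, lengths):
        intra = phenotype.intraburst_interval * (
            1.0 + rng.normal(0.0, 0.03, int(k))
        )  # ~3% intraburst dispersion
        intra[0] = 0.0
        spikes.append(t_ev + np.cumsum(intra))
    out = np.sort(np.concatenate(spikes))
    out = out[(out >= span[0]) & (out < span[1])]
    return _enforce_dead_time(out, ABS_REFRACTORY)


# ---------------------------------------------------------------------------
# waveforms


def waveform_template(ttp: float, sample_rate: float, n_samples: int, trough_at: float):
    """Biphasic extracellular template: negative trough then positive peak
    separated by ``ttp`` seconds; widths scale with ttp so that narrower
    spikes carry more high-frequency energy (a 0.5 ms template has its
    spectral 50%-rolloff near 2 kHz, matching the field's t_TTP/f50
    correspondence).

    The peak-to-peak separation of the *sum* of two lobes differs slightly
    from the lobe-center separation, so the second lobe's center is
    calibrated so that the realized trough-to-peak time equals ``ttp``.
    """
    s1 = ttp / 4.5
    s2 = ttp / 3.0

    def build(sep, t):
        return -np.exp(-0.5 * (t / s1) ** 2) + 0.55 * np.exp(-0.5 * ((t - sep) / s2) ** 2)

    # calibrate on a fine grid so grid quantization does not bias the fit
    tf = np.linspace(-6 * ttp, 8 * ttp, 4001)
    sep = ttp
    for _ in range(4):
        w = build(sep, tf)
        realized = tf[np.argmin(w) :][np.argmax(w[np.argmin(w) :])] - tf[np.argmin(w)]
        sep += ttp - realized
    t = np.arange(n_samples) / sample_rate - trough_at
    return build(sep, t)


def synth_waveform(
    phenotype: UnitPhenotype,
    n_spikes: int,
    sample_rate: float,
    rng: np.random.Generator | int,
    n_samples: int = 590,
    trough_at: float = 0.014,
) -> np.ndarray:
    """Matrix (n_spikes x n_samples) of noisy copies of the phenotype's
    biphasic template, with +/-1 sample alignment jitter."""
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    base = waveform_template(phenotype.waveform_ttp, sample_rate, n_samples, trough_at)
    out = np.empty((n_spikes, n_samples))
    for i in range(n_spikes):
        shift = rng.integers(-1, 2)
        out[i] = np.roll(base, shift) + rng.normal(0.0, phenotype.waveform_noise, n_samples)
    return out


# ---------------------------------------------------------------------------
# session assembly

PROTOCOL_NAMES = ("tuning", "duration_series", "ramp_series", "SAM_series", "vocal_list")

N_REPS = 10
PRESTIM = 0.200  # s
POSTSTIM = 0.300  # s


def _session_stimuli(protocols, rng: np.random.Generator):
    """Stimulus descriptors + envelopes shared by every unit of the session."""
    stims: dict[str, StimulusDescriptor] = {}
    envs: dict[str, Envelope] = {}

    def add(sid, kind, env, **kw):
        stims[sid] = StimulusDescriptor(
            stimulus_id=sid, kind=kind, duration=env.duration, onset=0.0, **kw
        )
        envs[sid] = env

    for proto in protocols:
        if proto == "tuning":
            for i in range(5):
                add(f"tone{i:02d}", "tone", flat_envelope(0.2))
        elif proto == "duration_series":
            for d in DURATIONS:
                add(f"dur{int(round(d * 1000)):03d}", "duration_series", flat_envelope(d))
        elif proto == "ramp_series":
            for r in RAMP_TIMES:
                add(f"ramp{int(round(r * 1000)):02d}", "ramp", flat_envelope(0.2, r),
                    ramp_time=r)
        elif proto == "SAM_series":
            for f in SAM_RATES:
                add(f"sam{int(f):03d}", "SAM", sam_envelope(f, 0.5), mod_rate=f)
        elif proto == "vocal_list":
            for i in range(20):
                dur = float(np.exp(rng.uniform(np.log(0.4), np.log(1.0))))
                env = vocalization_envelope(
                    n_events=int(rng.integers(2, 7)),
                    duration=dur,
                    rng=rng,
                    trill=bool(rng.uniform() < 0.3),
                )
                add(f"voc{i:02d}", "vocalization", env)
        else:
            raise ValueError(f"unknown protocol {proto!r}")
    proto_of = {
        "tone": "tuning",
        "duration_series": "duration_series",
        "ramp": "ramp_series",
        "SAM": "SAM_series",
        "vocalization": "vocal_list",
    }
    return stims, envs, proto_of


def _drive_profile(env: Envelope, pheno: UnitPhenotype) -> tuple[np.ndarray, np.ndarray]:
    """(slope_component, envelope_component) of the drive, each scaled so the
    combined profile peaks at <= 1.

    The rising-slope component models transient, edge-triggered excitation
    and does not adapt; the envelope component is the sustained drive that
    the adaptation profile multiplies.
    """
    if pheno.slope_drive > 0:
        slope = env.rising_slope() ** pheno.phase_lock_kappa
        m = slope.max()
        slope_part = pheno.slope_drive * (slope / m if m > 0 else slope)
    else:
        slope_part = np.zeros_like(env.amplitude)
    env_part = (1.0 - pheno.slope_drive) * env.amplitude
    return slope_part, env_part


def _unit_gains(stims, pheno: UnitPhenotype, rng: np.random.Generator):
    """Per-stimulus response gain: tuning curves for tones, sparse lognormal
    selectivity for vocalizations, full gain for the timing protocols."""
    gains = {}
    tone_ids = sorted(s for s in stims if stims[s].kind == "tone")
    best = rng.integers(0, len(tone_ids)) if tone_ids else 0
    tuning_shape = np.array([1.0, 0.6, 0.35, 0.2, 0.1])
    for sid, st in stims.items():
        if st.kind == "tone":
            rank = abs(tone_ids.index(sid) - best)
            gains[sid] = float(tuning_shape[min(rank, len(tuning_shape) - 1)])
        elif st.kind == "vocalization":
            if pheno.selectivity > 0:
                # sparser gains for more selective phenotypes: which units a
                # stimulus recruits then carries real identity information
                g = float(
                    rng.lognormal(-1.2 * pheno.selectivity, 0.7 + 0.3 * pheno.selectivity)
                )
                gains[sid] = min(g, 1.5)
            else:
                gains[sid] = 1.0
        else:
            gains[sid] = 1.0
    return gains


def _adaptation(t: np.ndarray, pheno: UnitPhenotype) -> np.ndarray:
    f = pheno.sustained_fraction
    return f + (1.0 - f) * np.exp(-np.clip(t, 0, None) / pheno.adaptation_tau)


def _temporal_weight(env: Envelope, rng: np.random.Generator, knot_spacing: float = 0.15,
                     sigma: float = 0.9) -> np.ndarray:
    """Smooth random per-unit temporal weighting of a vocalization response.

    Real units respond preferentially to different moments within the same
    call; a lognormal profile on ~150 ms knots (mean-normalized) gives each
    unit its own temporal emphasis so that population responses carry
    non-redundant information across units and time bins.
    """
    n_knots = max(2, int(np.ceil(env.duration / knot_spacing)) + 1)
    knots_t = np.linspace(env.t[0], env.t[-1], n_knots)
    w = np.interp(env.t, knots_t, rng.lognormal(0.0, sigma, n_knots))
    return w / w.mean()


def _make_unit(
    uid: str,
    pheno: UnitPhenotype,
    stims,
    envs,
    proto_of,
    rng: np.random.Generator,
) -> UnitRecording:
    gains = _unit_gains(stims, pheno, rng)
    bursting = pheno.burst_prob > 0
    trains = []
    for sid in sorted(stims):
        st = stims[sid]
        env = envs[sid]
        span = (-PRESTIM, st.duration + POSTSTIM)
        slope_part, env_part = _drive_profile(env, pheno)
        if st.kind == "vocalization":
            w = _temporal_weight(env, rng)
            slope_part = slope_part * w
            env_part = env_part * w

        def rate_fn(t, slope_part=slope_part, env_part=env_part, env=env, g=gains[sid],
                    trial_gain=1.0):
            te = t - pheno.latency
            transient = np.interp(te, env.t, slope_part, left=0.0, right=0.0)
            sustained = np.interp(te, env.t, env_part, left=0.0, right=0.0)
            drive = transient + sustained * _adaptation(te, pheno)
            return pheno.spontaneous_rate + pheno.driven_rate * g * trial_gain * drive

        for rep in range(N_REPS):
            # trial-to-trial response-gain variability (mean-one lognormal)
            s = pheno.trial_gain_sd
            tg = float(rng.lognormal(-0.5 * s**2, s)) if s > 0 else 1.0
            fn = lambda t, tg=tg: rate_fn(t, trial_gain=tg)  # noqa: E731
            if bursting:
                times = bursting_train(fn, pheno, span, rng)
            else:
                times = poisson_train(fn, span, rng, jitter_sd=pheno.jitter_sd)
            trains.append(
                SpikeTrain(
                    times=times,
                    trial_span=span,
                    stimulus_id=sid,
                    repetition=rep,
                    protocol=proto_of[st.kind],
                )
            )
    waveforms = synth_waveform(pheno, n_spikes=40, sample_rate=24414.0, rng=rng)
    wf_times = np.arange(40) * 0.050  # widely spaced -> all isolated
    return UnitRecording(
        unit_id=uid,
        trains=trains,
        stimuli=dict(stims),
        waveforms=waveforms,
        waveform_sample_rate=24414.0,
        waveform_spike_times=wf_times,
        prestim_duration=PRESTIM,
        truth_type=pheno.type,
    )


def generate_benchmark_session(
    n_units_by_type: dict[str, int],
    protocols=PROTOCOL_NAMES,
    rng_seed: int = 0,
    phenotypes: dict[str, UnitPhenotype] | None = None,
) -> list[UnitRecording]:
    """Generate a labeled benchmark session.

    Every unit sees the same stimulus set (one envelope per stimulus, shared
    across units, as in a real experiment); units carry ``truth_type``.
    """
    for p in protocols:
        if p not in PROTOCOL_NAMES:
            raise ValueError(f"unknown protocol {p!r}")
    phenotypes = phenotypes or DEFAULT_PHENOTYPES
    ss = np.random.SeedSequence(rng_seed)
    stim_rng = np.random.default_rng(ss.spawn(1)[0])
    stims, envs, proto_of = _session_stimuli(protocols, stim_rng)

    units = []
    order = [t for t in ("RS", "FS", "Bu1", "Bu2") if n_units_by_type.get(t, 0) > 0]
    total = sum(n_units_by_type.get(t, 0) for t in order)
    child_seeds = ss.spawn(total + 1)[1:]
    i = 0
    for typ in order:
        pheno = phenotypes[typ]
        for j in range(n_units_by_type[typ]):
            rng = np.random.default_rng(child_seeds[i])
            units.append(_make_unit(f"{typ}_{j:03d}", pheno, stims, envs, proto_of, rng))
            i += 1
    return units
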