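"""Spike-waveform conditioning and width/spectral metrics.

The pipeline mirrors standard extracellular practice: broadband zero-phase
filtering of the snippets, selection of isolated spikes, alignment on the
largest voltage change, averaging, then two width measures — the
trough-to-peak time (t_TTP) and the high-side 50%-rolloff frequency of the
baseline-subtracted spike spectrum (f50).  t_TTP and f50 are inversely
related; the classification boundaries are 0.5 ms and 2 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

FIR_ORDER = 256
MIN_SNIPPETS = 5

ISOLATION_WINDOWS = {
    # purpose -> (seconds before, seconds after) that must be free of spikes
    "average": (0.005, 0.006),
    "spectrum": (0.010, 0.006),
    "illustrate": (0.005, 0.0),  # allows closely *following* spikes
}


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class AverageWaveform:
    samples: np.ndarray
    sample_rate: float
    n_spikes: int
    align_index: int  # sample index of the common alignment point


def zero_phase_filter(
    snippets: np.ndarray, sample_rate: float, band: tuple[float, float] = (1.0, 10000.0)
) -> np.ndarray:
    """Broadband FIR filtering run forward and reverse (zero net group delay).

    A 256th-order FIR bandpass; the band top is truncated below Nyquist when
    necessary.  The taps are re-centered to exact zero DC gain so that a DC
    offset is removed while in-band components pass at unit gain.  Snippets
    shorter than the filter warm-up (one filter order) are rejected.
    """
    x = np.atleast_2d(np.asarray(snippets, dtype=float))
    if x.shape[1] <= FIR_ORDER:
        raise InsufficientDataError(
            f"snippet length {x.shape[1]} does not cover the {FIR_ORDER}-sample filter warm-up"
        )
    nyq = sample_rate / 2.0
    hi = min(band[1], 0.95 * nyq)
    taps = signal.firwin(FIR_ORDER + 1, hi, fs=sample_rate)
    # impose the low band edge as an exact spectral null at DC: a 1 Hz FIR
    # edge is far below the resolution of 257 taps, so subtract a smooth
    # (Hann) kernel carrying the filter's DC gain — in-band gain stays
    # within 1% above a few hundred Hz while constants are fully removed.
    dc_kernel = np.hanning(FIR_ORDER + 1)
    dc_kernel /= dc_kernel.sum()
    taps = taps - dc_kernel * taps.sum()
    y = signal.filtfilt(taps, [1.0], x, axis=1, padlen=FIR_ORDER)
    return y if np.asarray(snippets).ndim == 2 else y[0]


def select_isolated_spikes(spike_times: np.ndarray, purpose: str = "average") -> np.ndarray:
    """Indices of spikes with no neighbor inside the purpose-specific
    exclusion window (before, after)."""
    if purpose not in ISOLATION_WINDOWS:
        raise ValueError(f"unknown purpose {purpose!r}")
    before, after = ISOLATION_WINDOWS[purpose]
    t = np.asarray(spike_times, dtype=float)
    keep = []
    for i, ti in enumerate(t):
        d = t - ti
        ok = True
        for j, dj in enumerate(d):
            if j == i:
                continue
            if -before < dj < after or dj == 0:
                ok = False
                break
        if ok:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def _align_shift(snippet: np.ndarray) -> int:
    """Sample index of the largest absolute voltage change (first difference,
    lightly smoothed so broadband noise does not dominate the slope
    estimate); ties break to the earliest sample."""
    d = np.abs(np.convolve(np.diff(snippet), np.ones(3) / 3.0, mode="same"))
    return int(np.argmax(d))


def align_and_average(snippets: np.ndarray, sample_rate: float) -> AverageWaveform:
    """Shift each snippet so its maximum |voltage change| sits at a common
    index, then average.  Requires at least 5 snippets; shifted-out samples
    are cropped to the common overlap."""
    x = np.atleast_2d(np.asarray(snippets, dtype=float))
    if x.shape[0] < MIN_SNIPPETS:
        raise InsufficientDataError(f"need >= {MIN_SNIPPETS} snippets, got {x.shape[0]}")
    marks = np.array([_align_shift(s) for s in x])
    target = int(np.median(marks))
    shifts = target - marks
    left = max(0, shifts.max())
    right = min(x.shape[1], x.shape[1] + shifts.min())
    if right - left < 8:
        raise InsufficientDataError("alignment shifts leave no common overlap")
    aligned = np.empty((x.shape[0], right - left))
    for i, (s, sh) in enumerate(zip(x, shifts)):
        aligned[i] = np.roll(s, sh)[left:right]
    return AverageWaveform(
        samples=aligned.mean(axis=0),
        sample_rate=sample_rate,
        n_spikes=x.shape[0],
        align_index=target - left,
    )


def width_metrics(w: AverageWaveform) -> dict:
    """t_TTP (trough to next upward peak) and half-amplitude duration (s).

    The trough is the global minimum; t_TTP runs to the first local maximum
    after it (``None`` if the snippet ends first).  Half-amplitude duration
    is measured at 50% of trough depth relative to a 1 ms pre-spike baseline
    (ending 0.5 ms before the trough), on a 10x cubic-spline interpolation.
    """
    v = w.samples
    fs = w.sample_rate
    trough = int(np.argmin(v))
    peaks, _ = signal.find_peaks(v[trough + 1 :])
    if peaks.size:
        peak = trough + 1 + int(peaks[0])
        t_ttp = (peak - trough) / fs
    else:
        t_ttp = None  # no post-trough upward peak within the snippet

    guard = int(round(0.0005 * fs))
    b1 = max(0, trough - guard - int(round(0.001 * fs)))
    b2 = max(b1 + 1, trough - guard)
    baseline = float(v[b1:b2].mean())
    half = baseline - 0.5 * (baseline - v[trough])

    t = np.arange(v.size) / fs
    fine_t = np.linspace(t[0], t[-1], v.size * 10)
    fine_v = CubicSpline(t, v)(fine_t)
    ft = int(np.argmin(np.abs(fine_t - t[trough])))
    below = fine_v <= half
    if not below[ft]:
        return {"t_ttp": t_ttp, "half_amp_dur": None}
    i0 = ft
    while i0 > 0 and below[i0 - 1]:
        i0 -= 1
    i1 = ft
    while i1 < below.size - 1 and below[i1 + 1]:
        i1 += 1
    return {
        "t_ttp": None if t_ttp is None else float(t_ttp),
        "half_amp_dur": float(fine_t[i1] - fine_t[i0]),
    }


def spectral_f50(
    w: AverageWaveform,
    segment_dur: float = 0.005,
    peak_floor_hz: float = 400.0,
) -> float | None:
    """High-side frequency at which the baseline-subtracted spike amplitude
    spectrum rolls off to 50% of its peak.

    Spike and baseline segments of equal length (default 5 ms, Hann-windowed)
    are taken around the trough and from the pre-spike period; spectra are
    subtracted, the peak located above 400 Hz, and the 50% crossing found by
    linear interpolation.  ``None`` when no crossing exists (e.g. spectrum
    peak in the last bin, or silence).
    """
    v = w.samples
    fs = w.sample_rate
    nseg = int(round(segment_dur * fs))
    trough = int(np.argmin(v))
    # shrink the equal-length segments if the snippet cannot host 2 x 5 ms
    # around the trough (s0 = trough - nseg//3 must leave a full baseline)
    nseg = min(nseg, (3 * trough) // 4, (3 * (v.size - trough)) // 2 - 1)
    if nseg < int(round(0.002 * fs)):
        return None
    s0 = trough - nseg // 3
    if s0 - nseg < 0 or s0 + nseg > v.size:
        return None
    spike = v[s0 : s0 + nseg]
    base = v[s0 - nseg : s0]
    win = np.hanning(nseg)
    sp = np.abs(np.fft.rfft((spike - spike.mean()) * win, n=4 * nseg))
    bs = np.abs(np.fft.rfft((base - base.mean()) * win, n=4 * nseg))
    freqs = np.fft.rfftfreq(4 * nseg, d=1.0 / fs)
    diff = sp - bs
    valid = freqs >= peak_floor_hz
    if not np.any(valid) or diff[valid].max() <= 0:
        return None
    pk_rel = int(np.argmax(diff[valid]))
    pk = np.nonzero(valid)[0][0] + pk_rel
    half = diff[pk] / 2.0
    for i in range(pk, diff.size - 1):
        if diff[i + 1] <= half:
            f0, f1 = freqs[i], freqs[i + 1]
            d0, d1 = diff[i], diff[i + 1]
            return float(f0 + (d0 - half) / (d0 - d1) * (f1 - f0))
    return None


def unit_waveform_metrics(
    snippets: np.ndarray,
    sample_rate: float,
    spike_times: np.ndarray | None = None,
) -> dict:
    """Full pipeline: filter, select isolated spikes, align, average, and
    measure t_TTP, half-amplitude duration and f50 for one unit.

    Returns NaNs when fewer than 5 isolated snippets are available.
    """
    out = {"t_ttp_ms": np.nan, "half_amp_ms": np.nan, "f50_hz": np.nan}
    if snippets is None or len(snippets) == 0:
        return out
    filt = zero_phase_filter(snippets, sample_rate)
    if spike_times is not None:
        idx = select_isolated_spikes(spike_times, "average")
        filt_avg = filt[idx] if idx.size else filt[:0]
        idx_sp = select_isolated_spikes(spike_times, "spectrum")
        filt_sp = filt[idx_sp] if idx_sp.size else filt[:0]
    else:
        filt_avg = filt_sp = filt
    try:
        avg = align_and_average(filt_avg, sample_rate)
    except InsufficientDataError:
        return out
    wm = width_metrics(avg)
    if wm["t_ttp"] is not None:
        out["t_ttp_ms"] = wm["t_ttp"] * 1000.0
    if wm["half_amp_dur"] is not None:
        out["half_amp_ms"] = wm["half_amp_dur"] * 1000.0
    try:
        avg_sp = align_and_average(filt_sp, sample_rate)
        f50 = spectral_f50(avg_sp)
    except InsufficientDataError:
        f50 = None
    if f50 is not None:
        out["f50_hz"] = f50
    return out
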