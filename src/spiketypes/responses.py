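"""PSTHs, responsiveness tests, adaptation, and SAM synchrony metrics.

The response window runs from 10 ms after stimulus onset to 50 ms after
offset (150 ms for vocalizations, which are long and can outlast their
driven firing).  Vector strength is computed excluding the first 50 ms of
the response so a pure onset burst does not register as phase-locking, and
is reported as 0 when the Rayleigh statistic 2*N*VS^2 does not exceed 13.8
(p < 0.001 under the uniform-phase null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import poisson

from .session import SpikeTrain, StimulusDescriptor, UnitRecording, slice_epoch

RAYLEIGH_CRIT = 13.8


def rayleigh_significant(rayleigh: float) -> bool:
    """Strictly greater than 13.8, with a relative epsilon so that a value
    mathematically equal to the criterion never passes through float noise."""
    return bool(rayleigh > RAYLEIGH_CRIT * (1.0 + 1e-9))
PSTH_BIN = 0.001  # s
PSTH_SIGMA = 0.005  # s
RESP_BIN = 0.005  # s, bins of the max-PSTH responsiveness test


@dataclass(frozen=True)
class PSTH:
    edges: np.ndarray  # s
    counts: np.ndarray  # raw counts summed over repetitions
    rate: np.ndarray  # smoothed rate, spk/s
    n_reps: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def smoothed_psth(
    trains: list[SpikeTrain] | list[np.ndarray],
    window: tuple[float, float],
    bin_width: float = PSTH_BIN,
    sigma: float = PSTH_SIGMA,
) -> PSTH:
    """1 ms-binned PSTH convolved with a Gaussian (sigma = 5 ms).

    Edge bins use truncated-kernel renormalization, so the integrated rate
    equals the spike count to high accuracy for spikes away from the edges.
    """
    t0, t1 = window
    edges = np.arange(t0, t1 + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    n = 0
    for tr in trains:
        times = tr.times if isinstance(tr, SpikeTrain) else np.asarray(tr, float)
        c, _ = np.histogram(times, bins=edges)
        counts += c
        n += 1
    n = max(n, 1)
    rate = counts / (n * bin_width)
    s = sigma / bin_width
    sm = gaussian_filter1d(rate, s, mode="constant")
    norm = gaussian_filter1d(np.ones_like(rate), s, mode="constant")
    return PSTH(edges=edges, counts=counts, rate=sm / norm, n_reps=n)


def response_window(stim: StimulusDescriptor) -> tuple[float, float]:
    """[onset+10 ms, offset+50 ms), extended to offset+150 ms for vocalizations."""
    tail = 0.150 if stim.kind == "vocalization" else 0.050
    return (stim.onset + 0.010, stim.offset + tail)


def _prestim_rates(unit: UnitRecording) -> np.ndarray:
    """Firing rate in each trial's prestimulus segment, across all stimuli,
    repetitions and protocols."""
    T = unit.prestim_duration
    return np.array(
        [slice_epoch(tr, (-T, 0.0)).n_spikes / T for tr in unit.trains]
    )


def spontaneous_rate(unit: UnitRecording) -> float:
    """Mean rate over all pooled prestimulus segments (spk/s)."""
    r = _prestim_rates(unit)
    return float(r.mean()) if r.size else 0.0


def driven_rate(unit: UnitRecording, stimulus_id: str) -> float:
    """Mean rate (spk/s) over the response window, averaged over repetitions."""
    stim = unit.stimuli[stimulus_id]
    w = response_window(stim)
    trains = unit.trains_for(stimulus_id)
    if not trains:
        return 0.0
    counts = [slice_epoch(tr, w).n_spikes for tr in trains]
    return float(np.mean(counts) / (w[1] - w[0]))


def responsive_by_rate(unit: UnitRecording, stimulus_id: str) -> bool:
    """Excitatory rate response: driven rate exceeds the prestimulus mean
    plus 3 standard errors, with the variance rescaled by T_pre/T_resp to
    account for the longer averaging window."""
    pre = _prestim_rates(unit)
    if pre.size == 0:
        raise ValueError("no prestimulus data")
    stim = unit.stimuli[stimulus_id]
    w = response_window(stim)
    n_reps = len(unit.trains_for(stimulus_id))
    if n_reps == 0:
        return False
    se = np.sqrt(pre.var() * (unit.prestim_duration / (w[1] - w[0])) / n_reps)
    return driven_rate(unit, stimulus_id) > pre.mean() + 3.0 * se


def responsive_by_psth(unit: UnitRecording, stimulus_id: str) -> bool:
    """Instantaneous-rate response: the maximum 5 ms PSTH bin (counts
    aggregated across repetitions) is improbable under a Poisson fit to the
    spontaneous counts, Bonferroni-corrected for the number of bins."""
    stim = unit.stimuli[stimulus_id]
    w = response_window(stim)
    trains = unit.trains_for(stimulus_id)
    if not trains:
        return False
    n_reps = len(trains)
    edges = np.arange(w[0], w[1] + RESP_BIN / 2, RESP_BIN)
    counts = np.zeros(edges.size - 1)
    for tr in trains:
        c, _ = np.histogram(tr.times, bins=edges)
        counts += c
    n_bins = counts.size
    lam = spontaneous_rate(unit) * RESP_BIN * n_reps
    if lam <= 0:
        lam = 0.5  # floor: avoids a degenerate p-value with silent prestim
    p = poisson.sf(counts.max() - 1, lam)
    return bool(p < 0.01 / n_bins)


def adaptation_index(unit: UnitRecording, stimulus_id: str) -> float:
    """(r_early - r_late) / (r_early + r_late) for a 200 ms stimulus:
    early = [onset+10, onset+110) ms, late = last 100 ms of the offset-by-10
    response.  NaN when both rates are zero."""
    stim = unit.stimuli[stimulus_id]
    if stim.duration < 0.2 - 1e-9:
        raise ValueError("adaptation index requires a stimulus >= 200 ms")
    early = (stim.onset + 0.010, stim.onset + 0.110)
    late = (stim.onset + stim.duration + 0.010 - 0.100, stim.onset + stim.duration + 0.010)
    ne = nl = 0
    for tr in unit.trains_for(stimulus_id):
        ne += slice_epoch(tr, early).n_spikes
        nl += slice_epoch(tr, late).n_spikes
    if ne + nl == 0:
        return float("nan")
    return (ne - nl) / (ne + nl)


def vector_strength(phases: np.ndarray) -> float:
    if phases.size == 0:
        return float("nan")
    return float(np.abs(np.exp(1j * phases).mean()))


def vs_profile(unit: UnitRecording) -> list[dict]:
    """Per-SAM-rate vector strength and Rayleigh statistics.

    Spikes from onset+50 ms to stimulus offset are folded at the modulation
    rate; VS_reported is zeroed when 2*N*VS^2 <= 13.8 (strict inequality
    required for significance).
    """
    rows = []
    sam = sorted(
        (s for s in unit.stimuli.values() if s.kind == "SAM"), key=lambda s: s.mod_rate
    )
    for stim in sam:
        f = stim.mod_rate
        spikes = []
        for tr in unit.trains_for(stim.stimulus_id):
            seg = slice_epoch(tr, (stim.onset + 0.050, stim.offset))
            spikes.append(seg.times - stim.onset)
        t = np.concatenate(spikes) if spikes else np.empty(0)
        n = int(t.size)
        vs = vector_strength((2 * np.pi * f * t) % (2 * np.pi))
        rayleigh = 2.0 * n * vs**2 if n else 0.0
        sig = rayleigh_significant(rayleigh)
        rows.append(
            {
                "mod_rate": f,
                "stimulus_id": stim.stimulus_id,
                "n_spikes": n,
                "vs": 0.0 if n == 0 else vs,
                "rayleigh": rayleigh,
                "significant": sig,
                "vs_reported": vs if sig else 0.0,
            }
        )
    return rows


def sam_summary(profile: list[dict], rate_responsive: list[bool] | None = None) -> dict:
    """Summary synchrony measures over a SAM rate profile.

    f_max interpolates the Rayleigh statistic (in log2 frequency, the rates
    being octave-spaced) between the highest significant rate and the next
    one, to its 13.8 crossing.  tBMF is the VS-weighted geometric mean of
    the peak reported VS and significant immediate neighbors (requires >= 2
    significant rates).  A unit with no qualifying VS but a rate response to
    some SAM stimulus is "unsynchronized"; with neither it is excluded
    (all-None summary).
    """
    rates = np.array([r["mod_rate"] for r in profile])
    sig = np.array([r["significant"] for r in profile])
    vs_rep = np.array([r["vs_reported"] for r in profile])
    ray = np.array([r["rayleigh"] for r in profile])
    rate_resp = (
        np.asarray(rate_responsive, bool)
        if rate_responsive is not None
        else np.zeros(rates.size, bool)
    )

    out: dict = {
        "f_max": None,
        "tbmf": None,
        "sync_4": False,
        "sync_16": False,
        "unsynchronized": False,
        "excluded": False,
    }
    qual = sig & (vs_rep > 0.1)
    out["sync_4"] = bool(np.any(qual & (rates >= 4.0) & (rates <= 512.0)))
    out["sync_16"] = bool(np.any(qual & (rates >= 16.0) & (rates <= 512.0)))

    if np.any(sig):
        i = int(np.max(np.nonzero(sig)[0]))
        if i == rates.size - 1 or rayleigh_significant(ray[i + 1]):
            out["f_max"] = float(rates[i])
        else:
            x0, x1 = np.log2(rates[i]), np.log2(rates[i + 1])
            y0, y1 = ray[i], ray[i + 1]
            out["f_max"] = float(2 ** (x0 + (y0 - RAYLEIGH_CRIT) / (y0 - y1) * (x1 - x0)))
        if np.sum(sig) >= 2:
            pk = int(np.argmax(np.where(sig, vs_rep, -np.inf)))
            idx = [pk] + [j for j in (pk - 1, pk + 1) if 0 <= j < rates.size and sig[j]]
            w = vs_rep[idx]
            out["tbmf"] = float(np.exp(np.sum(w * np.log(rates[idx])) / np.sum(w)))
    elif np.any(rate_resp):
        out["unsynchronized"] = True
    else:
        out["excluded"] = True
    return out


def period_histogram(
    unit: UnitRecording, mod_rate: float, n_bins: int = 32
) -> tuple[np.ndarray, np.ndarray]:
    """Cycle histogram of spike phases at one SAM rate, normalized to unit
    area; returns (bin_edges_rad, density)."""
    stim = next(
        s
        for s in unit.stimuli.values()
        if s.kind == "SAM" and abs(s.mod_rate - mod_rate) < 1e-9
    )
    spikes = []
    for tr in unit.trains_for(stim.stimulus_id):
        seg = slice_epoch(tr, (stim.onset + 0.050, stim.offset))
        spikes.append(seg.times - stim.onset)
    t = np.concatenate(spikes) if spikes else np.empty(0)
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    counts, _ = np.histogram((2 * np.pi * mod_rate * t) % (2 * np.pi), bins=edges)
    width = edges[1] - edges[0]
    total = counts.sum()
    dens = counts / (total * width) if total else counts.astype(float)
    return edges, dens


def onset_latency(unit: UnitRecording, stimulus_ids: list[str] | None = None) -> float | None:
    """Minimum over responsive stimuli of the first post-onset time at which
    the smoothed PSTH exceeds the spontaneous mean + 3 SD; None when no
    stimulus is responsive."""
    pre = _prestim_rates(unit)
    if pre.size == 0:
        return None
    thresh = pre.mean() + 3.0 * pre.std()
    best = None
    ids = stimulus_ids if stimulus_ids is not None else sorted(unit.stimuli)
    for sid in ids:
        if not (responsive_by_rate(unit, sid) or responsive_by_psth(unit, sid)):
            continue
        stim = unit.stimuli[sid]
        trains = unit.trains_for(sid)
        if not trains:
            continue
        w = (stim.onset - unit.prestim_duration, response_window(stim)[1])
        p = smoothed_psth(trains, w)
        c = p.centers
        above = (c >= stim.onset) & (p.rate > thresh)
        if np.any(above):
            lat = float(c[np.argmax(above)] - stim.onset)
            best = lat if best is None else min(best, lat)
    return best
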