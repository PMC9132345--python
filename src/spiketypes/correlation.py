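"""Shuffled autocorrelogram and the normalized correlation index (CI).

The CI generalizes vector strength to aperiodic stimuli: it measures how
often spikes coincide across repetitions of the same stimulus, normalized
so that a homogeneous Poisson responder has CI ~ 1::

    CI(w) = N_c(w) / (M (M-1) r^2 w D)

with M repetitions, D the analysis-window duration, r the mean rate over
the analyzed window, and N_c the number of *ordered* cross-repetition spike
pairs with |dt| <= w/2.  Within-repetition pairs are excluded, which removes
refractory and intrinsic-burst structure.  The unit-level CI is the mean of
CI(w) over the 5 log-spaced coincidence windows flanking 0.5 ms, and CI_max
is the maximum over responsive stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import UnitRecording, slice_epoch
from .responses import response_window, responsive_by_psth, responsive_by_rate

#: w_k = 10^(k/10) ms over 0.05-5 ms (10 log-spaced samples per decade)
WINDOW_GRID = 10.0 ** (np.arange(-13, 8) / 10.0) / 1000.0  # s
#: indices of the 5 windows flanking 0.5 ms (two below, nearest, two above)
_CENTER = int(np.argmin(np.abs(WINDOW_GRID - 0.0005)))
FLANK_SLICE = slice(_CENTER - 2, _CENTER + 3)


@dataclass(frozen=True)
class SACurve:
    windows: np.ndarray  # s
    ci: np.ndarray
    n_pairs: np.ndarray  # ordered cross-trial pair counts per window
    m_reps: int
    duration: float
    rate: float


def shuffled_autocorrelogram(
    trains: list[np.ndarray], bin_width: float = 50e-6, lag_max: float = 0.020
) -> tuple[np.ndarray, np.ndarray]:
    """All-order cross-repetition interval histogram (the SAC).

    Counts ordered spike-time differences between all pairs of distinct
    repetitions; returns (bin_edges_s, counts) over [-lag_max, lag_max].
    """
    if len(trains) < 2:
        raise ValueError("shuffled autocorrelogram needs >= 2 repetitions")
    edges = np.arange(-lag_max, lag_max + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    arrs = [np.asarray(t, float) for t in trains]
    for i, a in enumerate(arrs):
        for j, b in enumerate(arrs):
            if i == j or a.size == 0 or b.size == 0:
                continue
            # windowed differences: for each spike in a, spikes of b nearby
            lo = np.searchsorted(b, a - lag_max, side="left")
            hi = np.searchsorted(b, a + lag_max, side="right")
            for t, l, h in zip(a, lo, hi):
                if h > l:
                    c, _ = np.histogram(b[l:h] - t, bins=edges)
                    counts += c
    return edges, counts


def _cross_pair_counts(trains: list[np.ndarray], half_windows: np.ndarray) -> np.ndarray:
    """Ordered cross-repetition pairs with |dt| <= half_window, per window."""
    out = np.zeros(half_windows.size, dtype=float)
    arrs = [np.asarray(t, float) for t in trains]
    wmax = float(half_windows.max())
    for i, a in enumerate(arrs):
        for j, b in enumerate(arrs):
            if j <= i or a.size == 0 or b.size == 0:
                continue
            lo = np.searchsorted(b, a - wmax, side="left")
            hi = np.searchsorted(b, a + wmax, side="right")
            diffs = []
            for t, l, h in zip(a, lo, hi):
                if h > l:
                    diffs.append(np.abs(b[l:h] - t))
            if diffs:
                d = np.concatenate(diffs)
                # unordered pairs counted once here; x2 for ordered pairs
                out += 2.0 * np.searchsorted(np.sort(d), half_windows, side="right")
    return out


def ci_curve(
    trains: list[np.ndarray], duration: float, windows: np.ndarray = WINDOW_GRID
) -> SACurve:
    """Correlation index versus coincidence window for one stimulus.

    ``trains`` are spike-time arrays of the M repetitions, restricted to
    (and referenced within) the analysis window of length ``duration``.
    Raises when fewer than 2 repetitions or no spikes (rate undefined).
    """
    m = len(trains)
    if m < 2:
        raise ValueError("CI needs >= 2 repetitions")
    total = int(sum(len(t) for t in trains))
    if total < 2 or duration <= 0:
        raise ValueError("CI undefined: no spikes or empty window")
    r = total / (m * duration)
    n_c = _cross_pair_counts(trains, np.asarray(windows) / 2.0)
    denom = m * (m - 1) * r**2 * np.asarray(windows) * duration
    return SACurve(
        windows=np.asarray(windows),
        ci=n_c / denom,
        n_pairs=n_c,
        m_reps=m,
        duration=duration,
        rate=r,
    )


def ci_at_half_ms(curve: SACurve) -> float:
    """Mean CI over the 5 grid windows flanking 0.5 ms."""
    return float(curve.ci[FLANK_SLICE].mean())


def ci_unit(
    unit: UnitRecording, stimulus_ids: list[str] | None = None
) -> dict:
    """Per-stimulus CI (at the 0.5 ms flank average) over responsive
    vocalization stimuli, and their maximum CI_max.

    Responsiveness is excitatory only, by overall rate or by maximum 5 ms
    PSTH bin.  Stimuli with no cross-repetition interval inside the largest
    window contribute no CI; a unit with no responsive stimuli (or no
    usable intervals at all) has CI_max None.
    """
    if stimulus_ids is None:
        stimulus_ids = sorted(
            s for s, st in unit.stimuli.items() if st.kind == "vocalization"
        )
    per_stim: dict[str, float] = {}
    for sid in stimulus_ids:
        if not (responsive_by_rate(unit, sid) or responsive_by_psth(unit, sid)):
            continue
        stim = unit.stimuli[sid]
        w = response_window(stim)
        arrs = [slice_epoch(tr, w).times - w[0] for tr in unit.trains_for(sid)]
        if len(arrs) < 2 or sum(len(a) for a in arrs) < 2:
            continue
        curve = ci_curve(arrs, duration=w[1] - w[0])
        if curve.n_pairs.max() == 0:
            continue  # no interval within any coincidence window
        per_stim[sid] = ci_at_half_ms(curve)
    return {
        "ci_per_stimulus": per_stim,
        "ci_max": max(per_stim.values()) if per_stim else None,
        "n_responsive": len(per_stim),
    }
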