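"""ISI-, autocorrelogram- and burst-based features of a unit's spike timing.

Conventions
-----------
* ISI histograms use 0.2 ms linear bins, or 0.1-wide bins of the *natural*
  log of the ISI expressed in milliseconds.  The ln(ms) convention is fixed
  by the Poisson anchors: a 50 spk/s unit has its log-ISI mode at
  ln(20 ms) ~ 3 and a 1 spk/s unit at ln(1000 ms) ~ 7.
* The log-ISI peak is read below 80 ms only, to avoid secondary peaks
  created by the log transform and by the trial repetition period.
* Autocorrelograms count ordered pairs at positive lags within each
  contiguous segment (never across trial boundaries); self-pairs excluded;
  0.2 ms bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

LINEAR_BIN_MS = 0.2
LOG_BIN = 0.1  # in ln(ms) units
ISI_PEAK_CEILING_MS = 80.0
MIN_INTERVALS = 50


class InsufficientDataError(ValueError):
    """Fewer intervals/spikes than the analysis requires."""


@dataclass(frozen=True)
class ISIHistogram:
    """bin edges are in ms (linear scale) or ln(ms) (log scale)."""

    edges: np.ndarray
    counts: np.ndarray
    scale: str  # "linear" | "log"
    n_intervals: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class Autocorrelogram:
    """lag bin edges in ms; counts over positive lags, self-pairs excluded."""

    edges: np.ndarray
    counts: np.ndarray


def isi_histogram(intervals: np.ndarray, scale: str = "linear") -> ISIHistogram:
    """Histogram of ISIs (input in seconds).

    Log-scale edges are anchored at integer multiples of 0.1 in ln(ms) and
    always extend past ln(16 ms) so the burst-score reference region exists
    even when unoccupied.
    """
    iv = np.asarray(intervals, dtype=float)
    if iv.size and iv.min() <= 0:
        raise ValueError("intervals must be positive")
    iv_ms = iv * 1000.0
    # bin by integer index with a sub-nanosecond epsilon so values that are
    # exact bin-edge multiples land in the bin whose left edge they equal
    eps = 1e-6
    if scale == "linear":
        width = LINEAR_BIN_MS
        idx = np.floor(iv_ms / width + eps).astype(int) if iv.size else np.empty(0, int)
        n_bins = max(int(idx.max(initial=0)) + 1, 1)
        edges = np.arange(n_bins + 1) * width
        first = 0
    elif scale == "log":
        width = LOG_BIN
        x = np.log(iv_ms) if iv.size else iv_ms
        idx = np.floor(x / width + eps).astype(int) if iv.size else np.empty(0, int)
        first = min(int(idx.min(initial=0)), 0)
        last = max(int(idx.max(initial=0)), 28)  # always cover past ln(16 ms)
        edges = np.arange(first, last + 2) * width
        idx = idx - first
    else:
        raise ValueError(f"unknown scale {scale!r}")
    counts = np.bincount(idx, minlength=edges.size - 1) if iv.size else np.zeros(
        edges.size - 1, int
    )
    return ISIHistogram(edges=edges, counts=counts, scale=scale, n_intervals=int(iv.size))


def isi_peak(h: ISIHistogram) -> float:
    """Mode of the log-ISI histogram below 80 ms, returned in ms.

    Ties break toward the shorter ISI (conservative for burst detection).
    """
    if h.scale != "log":
        raise ValueError("isi_peak expects a log-scale histogram")
    if h.n_intervals < MIN_INTERVALS:
        raise InsufficientDataError(
            f"need >= {MIN_INTERVALS} intervals, got {h.n_intervals}"
        )
    centers = h.centers
    mask = centers < np.log(ISI_PEAK_CEILING_MS)
    counts = h.counts[mask]
    if counts.size == 0 or counts.max() == 0:
        raise InsufficientDataError("no intervals below the 80 ms ceiling")
    return float(np.exp(centers[mask][int(np.argmax(counts))]))


def refractory_period(h: ISIHistogram) -> float | None:
    """Left edge (s) of the smallest ISI bin whose count exceeds 1/200 of the
    histogram peak; ``None`` when no bin qualifies.

    For sparse low-rate units this can return a spuriously large value; it is
    a descriptive feature, not a physiological estimate.
    """
    if h.scale != "linear":
        raise ValueError("refractory_period expects a linear-scale histogram")
    if h.n_intervals == 0:
        raise InsufficientDataError("empty histogram")
    thresh = h.counts.max() / 200.0
    idx = np.nonzero(h.counts > thresh)[0]
    if idx.size == 0:
        return None
    return float(h.edges[idx[0]] / 1000.0)


def smoothed_log_hist(intervals: np.ndarray) -> ISIHistogram:
    """Log-ISI histogram with Savitzky-Golay smoothing (window 5, degree 3)
    applied to the full histogram; smoothed counts may go negative."""
    h = isi_histogram(intervals, scale="log")
    sm = savgol_filter(h.counts.astype(float), 5, 3) if h.counts.size >= 5 else h.counts.astype(float)
    return ISIHistogram(edges=h.edges, counts=sm, scale="log", n_intervals=h.n_intervals)


def log_isi_drop(intervals: np.ndarray) -> float:
    """Burst score contrasting the smoothed log-ISI histogram's 1-5 ms peak
    against its mean level over 10-16 ms (5 bins)::

        (max y[ln1, ln5] - mean y[ln10, ln16]) / (max + mean)

    Normally in [-1, 1]; smoothing can rarely push it beyond.  Requires at
    least 50 intervals.  Input in seconds.
    """
    iv = np.asarray(intervals, dtype=float)
    if iv.size < MIN_INTERVALS:
        raise InsufficientDataError(f"need >= {MIN_INTERVALS} intervals, got {iv.size}")
    h = smoothed_log_hist(iv)
    c = h.centers
    peak_region = h.counts[(c >= np.log(1.0) - 1e-9) & (c <= np.log(5.0))]
    ref_region = h.counts[(c >= np.log(10.0)) & (c <= np.log(16.0))]
    peak = float(peak_region.max(initial=0.0))
    ref = float(ref_region.mean()) if ref_region.size else 0.0
    denom = peak + ref
    if denom == 0:
        return 0.0
    return (peak - ref) / denom


def autocorrelogram(
    segments: list[np.ndarray], lag_max: float = 0.080, bin_width: float = 0.0002
) -> Autocorrelogram:
    """Autocorrelogram over positive lags, counting ordered pairs within each
    contiguous segment only (no pairs across trial boundaries).

    ``segments`` is a list of sorted spike-time arrays (s), one per trial or
    contiguous recording segment.
    """
    edges_ms = np.arange(0.0, lag_max * 1000.0 + bin_width * 1000.0, bin_width * 1000.0)
    counts = np.zeros(edges_ms.size - 1, dtype=float)
    for seg in segments:
        seg = np.asarray(seg, float)
        if seg.size < 2:
            continue
        hi = np.searchsorted(seg, seg + lag_max, side="right")
        for i in range(seg.size - 1):
            lags = seg[i + 1 : hi[i]] - seg[i]
            if lags.size:
                c, _ = np.histogram(lags * 1000.0, bins=edges_ms)
                counts += c
    return Autocorrelogram(edges=edges_ms, counts=counts)


def autocorrelogram_metric(ac: Autocorrelogram) -> float | None:
    """Contrast of mean autocorrelogram height below 8 ms vs 35-80 ms::

        ACM = (R(0,8) - R(35,80)) / (R(0,8) + R(35,80))

    ``None`` when both means are zero.  Invariant to uniform count rescaling.
    """
    centers = 0.5 * (ac.edges[:-1] + ac.edges[1:])
    short = ac.counts[(centers >= 0.0) & (centers < 8.0)]
    long = ac.counts[(centers >= 35.0) & (centers < 80.0)]
    a = float(short.mean()) if short.size else 0.0
    b = float(long.mean()) if long.size else 0.0
    if a + b == 0:
        return None
    return (a - b) / (a + b)


def intraburst_frequency(h: ISIHistogram) -> float:
    """Inverse of the linear (non-log) ISI-histogram peak, in Hz.

    A 1.3 ms peak gives 769 Hz; 2.0 ms gives exactly 500 Hz (the boundary
    between high- and low-frequency bursting subgroups).
    """
    if h.scale != "linear":
        raise ValueError("intraburst_frequency expects a linear-scale histogram")
    if h.n_intervals < MIN_INTERVALS:
        raise InsufficientDataError(
            f"need >= {MIN_INTERVALS} intervals, got {h.n_intervals}"
        )
    peak_center_ms = float(h.centers[int(np.argmax(h.counts))])
    return 1000.0 / peak_center_ms


def burst_stats(intervals: np.ndarray, isi_peak_ms: float) -> dict:
    """Burst-run and regularity statistics from ISIs (s).

    A burst is a maximal run of consecutive ISIs within [0.5, 1.5] x the ISI
    peak; its length is counted in spikes (a run of one ISI = 2 spikes).
    ``pct_normalized`` divides the percentage of ISIs < 5 ms by that expected
    for a Poisson process with the same mean rate (r = 1 / mean ISI);
    ``regularity`` is Var[ISI_n / (ISI_n + ISI_{n+1})] (0 for a perfectly
    periodic train).
    """
    iv = np.asarray(intervals, dtype=float)
    if iv.size < 2:
        raise InsufficientDataError("need >= 2 intervals")
    in_burst = (iv >= 0.5 * isi_peak_ms / 1000.0) & (iv <= 1.5 * isi_peak_ms / 1000.0)
    lengths = []
    run = 0
    for flag in in_burst:
        if flag:
            run += 1
        elif run:
            lengths.append(run + 1)
            run = 0
    if run:
        lengths.append(run + 1)
    pct_lt5 = 100.0 * float(np.mean(iv < 0.005))
    r = 1.0 / float(iv.mean())
    expected_pct = 100.0 * (1.0 - np.exp(-r * 0.005))
    ratios = iv[:-1] / (iv[:-1] + iv[1:])
    return {
        "mean_burst_len": float(np.mean(lengths)) if lengths else 0.0,
        "max_burst_len": int(max(lengths)) if lengths else 0,
        "pct_isi_lt_5ms": pct_lt5,
        "pct_normalized": pct_lt5 / expected_pct if expected_pct > 0 else np.nan,
        "regularity": float(np.var(ratios)),
    }


# ---------------------------------------------------------------------------
# Hartigan's dip test


def _lower_hull(xs: np.ndarray, ys: np.ndarray):
    """Indices of the lower convex hull of (xs, ys); xs strictly increasing."""
    hull = []
    for i in range(len(xs)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # pop b if it lies on/above the chord a->i
            if (ys[b] - ys[a]) * (xs[i] - xs[a]) >= (ys[i] - ys[a]) * (xs[b] - xs[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan & Hartigan's dip: the maximum distance between the empirical
    CDF and the closest unimodal CDF.

    Computed by the iterative greatest-convex-minorant / least-concave-
    majorant narrowing of the modal interval.  Always >= 1/(2n); equals 1/4
    for a two-point sample.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0

    # collapse duplicates: each distinct value keeps its total ECDF mass
    ux, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts)  # ECDF numerator after the jump at each ux
    m = ux.size
    F_hi = cum / n  # F(x_j)
    F_lo = (cum - counts) / n  # F(x_j^-)
    if m == 1:
        return 0.0

    lo, hi = 0, m - 1
    D = 0.0
    while True:
        idx = np.arange(lo, hi + 1)
        xs = ux[idx]
        # gcm: greatest convex function <= F; constraint F(x_j^-) except at lo
        gy = F_lo[idx].copy()
        gy[0] = F_hi[lo]
        g_hull = _lower_hull(xs, gy)
        g_vals = np.interp(xs, xs[g_hull], gy[g_hull])
        # lcm: least concave function >= F; constraint F(x_j)
        ly = F_hi[idx]
        l_hull = _lower_hull(xs, -ly)  # upper hull via negation
        l_vals = np.interp(xs, xs[l_hull], ly[l_hull])

        gap = l_vals - g_vals
        j_rel = int(np.argmax(gap))
        d = float(gap[j_rel])
        if d <= D:
            break
        if hi - lo <= 1:
            D = max(D, d)
            break

        g_touch = np.asarray(g_hull)
        l_touch = np.asarray(l_hull)
        if j_rel in set(g_hull):
            new_lo_rel = j_rel
            cand = l_touch[l_touch >= j_rel]
            new_hi_rel = int(cand[0]) if cand.size else hi - lo
        else:
            new_hi_rel = j_rel
            cand = g_touch[g_touch <= j_rel]
            new_lo_rel = int(cand[-1]) if cand.size else 0

        # deviations in the regions excluded from the modal interval
        left_dev = float((F_hi[idx] - g_vals)[: new_lo_rel + 1].max(initial=0.0))
        right_dev = float((l_vals - F_lo[idx])[new_hi_rel:].max(initial=0.0))
        D = max(D, left_dev, right_dev)

        new_lo, new_hi = lo + new_lo_rel, lo + new_hi_rel
        if (new_lo, new_hi) == (lo, hi):
            D = max(D, d)
            break
        lo, hi = new_lo, new_hi

    return max(D / 2.0, 1.0 / (2.0 * n))


_DIP_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def dip_test(
    values: np.ndarray, n_boot: int = 2000, rng_seed: int = 0
) -> dict:
    """Dip statistic plus a bootstrap p-value under the uniform null.

    The null distribution of the dip depends only on the sample size, so it
    is simulated from U(0,1) samples (seeded; >= 2000 replicates by default)
    and cached per (n, n_boot, seed).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise InsufficientDataError("dip test needs at least 10 values")
    d = dip_statistic(x)
    key = (x.size, n_boot, rng_seed)
    if key not in _DIP_NULL_CACHE:
        rng = np.random.default_rng(rng_seed)
        null = np.array(
            [dip_statistic(rng.uniform(0, 1, x.size)) for _ in range(n_boot)]
        )
        _DIP_NULL_CACHE[key] = np.sort(null)
    null = _DIP_NULL_CACHE[key]
    p = float((np.sum(null >= d) + 1) / (null.size + 1))
    return {"dip": d, "p": p}
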