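"""Victor-Purpura spike-train metric and single-unit stimulus decoding.

The Victor-Purpura distance is the minimum cost of editing one spike train
into another, with insertion/deletion cost 1 per spike and a shift cost of
q*|dt| per second of displacement; shifting is only worthwhile for
|dt| < 2/q.  At q = 0 the distance reduces to the spike-count difference
(a pure rate code); large q demands temporal precision.

Decoding assigns each train to the stimulus with the smallest power-mean
distance (exponent z = -3) to the other repetitions, the train itself
excluded; ties are tallied fractionally.  The quality of the resulting
confusion matrix is summarized by its transmitted information H (bits).
"""

from __future__ import annotations

import numpy as np

from .session import UnitRecording, slice_epoch
from .responses import response_window

DEFAULT_Q_GRID = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0,
                  512.0, 1024.0, 2048.0, 4096.0)
KDE_SIGMA = 0.020  # s, bandwidth of the response-centering density estimate


def vp_distance(a: np.ndarray, b: np.ndarray, q: float) -> float:
    """Exact Victor-Purpura distance by dynamic programming.

    ``a`` and ``b`` are sorted spike-time arrays (s); q in 1/s.
    d(a, a) = 0; d at q = 0 is |n_a - n_b|; d <= n_a + n_b always.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        return float(na + nb)
    if q == 0.0:
        return float(abs(na - nb))
    prev = np.arange(nb + 1, dtype=float)  # row i=0: delete all of b's prefix
    cur = np.empty(nb + 1, dtype=float)
    for i in range(1, na + 1):
        cur[0] = i
        shift = q * np.abs(a[i - 1] - b)
        for j in range(1, nb + 1):
            cur[j] = min(prev[j] + 1.0, cur[j - 1] + 1.0, prev[j - 1] + shift[j - 1])
        prev, cur = cur, prev
    return float(prev[nb])


def distance_matrix(trains: list[np.ndarray], q: float) -> np.ndarray:
    """Symmetric pairwise Victor-Purpura distance matrix."""
    n = len(trains)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = vp_distance(trains[i], trains[j], q)
    return D


def crop_and_center(
    trains_by_stim: dict[str, list[np.ndarray]],
    durations: dict[str, float],
    target_len: float,
) -> dict[str, list[np.ndarray]]:
    """Crop every stimulus's responses to a segment of ``target_len`` (the
    shortest stimulus duration) centered on the peak of a Gaussian kernel
    density estimate of the pooled response, clipped to the stimulus window;
    spikes are re-referenced to the segment start.

    A stimulus with no spikes anchors its segment at the window start.
    """
    out = {}
    for sid, reps in trains_by_stim.items():
        dur = durations[sid]
        pooled = np.concatenate([r for r in reps]) if reps else np.empty(0)
        if pooled.size == 0 or dur <= target_len:
            start = 0.0
        else:
            grid = np.arange(0.0, dur, 0.001)
            dens = np.zeros_like(grid)
            for t in pooled:
                dens += np.exp(-0.5 * ((grid - t) / KDE_SIGMA) ** 2)
            peak = grid[int(np.argmax(dens))]
            start = min(max(peak - target_len / 2.0, 0.0), dur - target_len)
        out[sid] = [
            r[(r >= start) & (r < start + target_len)] - start for r in reps
        ]
    return out


def classify_trains(
    trains_by_stim: dict[str, list[np.ndarray]], q: float, z_exp: float = -3.0
) -> np.ndarray:
    """Leave-one-out nearest-stimulus classification at cost q.

    For each train, the distance to a stimulus is the power mean (exponent
    z = -3) of its distances to that stimulus's *other* repetitions; any
    zero distance maps the whole average to 0 (the transformation's known
    distortion, applied literally).  Ties are tallied 1/k.  Returns the
    confusion matrix (true x decoded), rows ordered by sorted stimulus id.
    """
    sids = sorted(trains_by_stim)
    if len(sids) < 2:
        raise ValueError("need >= 2 stimuli")
    usable = [s for s in sids if len(trains_by_stim[s]) >= 2]
    if len(usable) < len(sids):
        sids = usable
        if len(sids) < 2:
            raise ValueError("need >= 2 stimuli with >= 2 repetitions")
    all_trains = []
    labels = []
    for s in sids:
        for r in trains_by_stim[s]:
            all_trains.append(np.asarray(r, float))
            labels.append(s)
    labels = np.asarray(labels)
    D = distance_matrix(all_trains, q)
    return _confusion_from_distances(D, labels, sids, z_exp)


def _confusion_from_distances(
    D: np.ndarray, labels: np.ndarray, sids: list, z_exp: float
) -> np.ndarray:
    S = len(sids)
    cm = np.zeros((S, S))
    sid_index = {s: k for k, s in enumerate(sids)}
    for i in range(D.shape[0]):
        avg = np.empty(S)
        for k, s in enumerate(sids):
            mask = (labels == s)
            mask[i] = False
            d = D[i, mask]
            if d.size == 0:
                avg[k] = np.inf
            elif np.any(d == 0.0):
                avg[k] = 0.0
            else:
                avg[k] = np.mean(d**z_exp) ** (1.0 / z_exp)
        best = np.flatnonzero(avg == avg.min())
        for k in best:
            cm[sid_index[labels[i]], k] += 1.0 / best.size
    return cm


def transmitted_information(cm: np.ndarray) -> float:
    """Mutual information (bits) of a confusion matrix; 0 log 0 = 0."""
    cm = np.asarray(cm, float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p = cm / total
    ps = p.sum(axis=1, keepdims=True)
    pr = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (ps * pr))
    return float(np.nansum(terms))


def q_sweep(
    trains_by_stim: dict[str, list[np.ndarray]],
    q_grid=DEFAULT_Q_GRID,
    n_shuffles: int = 100,
    z_thresh: float = 3.0,
    rng_seed: int = 0,
) -> dict:
    """Transmitted information versus cost q, with a label-shuffle null.

    Distances are computed once per q; the shuffle null (100 label
    permutations at the unit's best q) reuses them.  The unit is flagged
    for inclusion when its best H exceeds the null mean by ``z_thresh``
    standard deviations.  The normalized curve is H(q)/max H(q).
    """
    sids = sorted(s for s in trains_by_stim if len(trains_by_stim[s]) >= 2)
    if len(sids) < 2:
        raise ValueError("need >= 2 stimuli with >= 2 repetitions")
    all_trains, labels = [], []
    for s in sids:
        for r in trains_by_stim[s]:
            all_trains.append(np.asarray(r, float))
            labels.append(s)
    labels = np.asarray(labels)
    if all(len(t) == 0 for t in all_trains):
        raise ValueError("all responses empty")

    H = np.empty(len(q_grid))
    Ds = {}
    for qi, q in enumerate(q_grid):
        D = distance_matrix(all_trains, q)
        Ds[q] = D
        H[qi] = transmitted_information(
            _confusion_from_distances(D, labels, sids, -3.0)
        )
    best_qi = int(np.argmax(H))
    best_q = q_grid[best_qi]

    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_shuffles)
    D = Ds[best_q]
    for s in range(n_shuffles):
        perm = rng.permutation(labels)
        null[s] = transmitted_information(
            _confusion_from_distances(D, perm, sids, -3.0)
        )
    sd = null.std()
    z = (H[best_qi] - null.mean()) / sd if sd > 0 else np.inf
    hmax = H.max()
    return {
        "q_grid": np.asarray(q_grid, float),
        "H": H,
        "H_normalized": H / hmax if hmax > 0 else H,
        "best_q": float(best_q),
        "null_mean": float(null.mean()),
        "null_sd": float(sd),
        "z": float(z),
        "include": bool(z > z_thresh),
    }


def unit_vp_decoding(
    unit: UnitRecording,
    stimulus_ids: list[str] | None = None,
    q_grid=DEFAULT_Q_GRID,
    n_shuffles: int = 100,
    rng_seed: int = 0,
) -> dict:
    """Crop-and-center the unit's vocalization responses, then sweep q.

    Uses the full stimulus set (rate coding can exploit unresponsive
    stimuli); segments are cut to the shortest stimulus duration.
    """
    if stimulus_ids is None:
        stimulus_ids = sorted(
            s for s, st in unit.stimuli.items() if st.kind == "vocalization"
        )
    durations = {s: unit.stimuli[s].duration for s in stimulus_ids}
    target = min(durations.values())
    trains_by_stim = {}
    for sid in stimulus_ids:
        stim = unit.stimuli[sid]
        w = (stim.onset, stim.offset)
        trains_by_stim[sid] = [
            slice_epoch(tr, w).times - stim.onset for tr in unit.trains_for(sid)
        ]
    cropped = crop_and_center(trains_by_stim, durations, target)
    return q_sweep(cropped, q_grid=q_grid, n_shuffles=n_shuffles, rng_seed=rng_seed)
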