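"""Pseudopopulation construction and time-binned population decoding.

Units were not recorded simultaneously, so population responses are
assembled by sampling, for each unit independently, one repetition as the
left-out test trial; the remaining repetitions form that unit's class
templates.  Responses are spike counts in nonoverlapping time bins
(default 10 ms) over a window cropped to the shortest stimulus duration
plus 300 ms (short stimuli are effectively zero-padded).

Two decoders are provided: maximum correlation coefficient (MCC) against
class-mean templates, and shrinkage-regularized LDA with a uniform prior.
The ``avg_time`` manipulation collapses each unit's response to its mean
over bins (a pure rate code); ``avg_units`` averages across units while
preserving bins (a pooled temporal response).
"""

from __future__ import annotations

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .session import UnitRecording, slice_epoch

DEFAULT_BIN = 0.010  # s
CROP_TAIL = 0.300  # s beyond the shortest stimulus
#: RS : Bu prevalence in mixed pseudopopulations (as observed prevalence)
MIXTURE_RATIO = (110, 54)


def bin_responses(
    units: list[UnitRecording],
    stimulus_ids: list[str],
    bin_width: float = DEFAULT_BIN,
) -> np.ndarray:
    """Count tensor (unit, stimulus, repetition, bin) over the cropped window.

    The window is [0, shortest stimulus duration + 300 ms); bins are
    half-open; repetitions are assumed aligned across units (same stimulus
    set), and every unit must have the same repetition count.
    """
    shortest = min(units[0].stimuli[s].duration for s in stimulus_ids)
    t1 = shortest + CROP_TAIL
    edges = np.arange(0.0, t1 + bin_width / 2, bin_width)
    n_bins = edges.size - 1
    n_reps = len(units[0].trains_for(stimulus_ids[0]))
    X = np.zeros((len(units), len(stimulus_ids), n_reps, n_bins))
    for ui, u in enumerate(units):
        for si, sid in enumerate(stimulus_ids):
            trains = u.trains_for(sid)
            if len(trains) != n_reps:
                raise ValueError(
                    f"unit {u.unit_id} has {len(trains)} reps of {sid}, expected {n_reps}"
                )
            for ri, tr in enumerate(trains):
                stim = u.stimuli[sid]
                seg = slice_epoch(tr, (stim.onset, stim.onset + t1)).times - stim.onset
                X[ui, si, ri], _ = np.histogram(seg, bins=edges)
    return X


def sample_pseudopopulation(
    pool_indices: np.ndarray,
    pool_types: np.ndarray,
    n_units: int,
    composition: str,
    n_reps: int,
    n_stimuli: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample units (without replacement) and per-unit-per-stimulus left-out
    test-repetition indices.

    composition: 'Bu' and 'RS' restrict to one type; 'mixture' draws RS and
    Bu at the observed prevalence ratio (~2:1).
    """
    pool_indices = np.asarray(pool_indices)
    pool_types = np.asarray(pool_types)
    if composition in ("Bu", "RS"):
        cand = pool_indices[pool_types == composition]
        if n_units > cand.size:
            raise ValueError(f"requested {n_units} units, pool has {cand.size}")
        chosen = rng.choice(cand, size=n_units, replace=False)
    elif composition == "mixture":
        n_rs = int(round(n_units * MIXTURE_RATIO[0] / sum(MIXTURE_RATIO)))
        n_bu = n_units - n_rs
        rs = pool_indices[pool_types == "RS"]
        bu = pool_indices[pool_types == "Bu"]
        if n_rs > rs.size or n_bu > bu.size:
            raise ValueError("pool too small for the requested mixture")
        chosen = np.concatenate(
            [rng.choice(rs, size=n_rs, replace=False), rng.choice(bu, size=n_bu, replace=False)]
        )
    else:
        raise ValueError(f"unknown composition {composition!r}")
    chosen = np.sort(chosen)  # fixed concatenation order for reproducibility
    test_idx = rng.integers(0, n_reps, size=(chosen.size, n_stimuli))
    return chosen, test_idx


def mcc_decode(templates: np.ndarray, test: np.ndarray, rng: np.random.Generator) -> int:
    """Index of the class template with the highest Pearson correlation to
    the test vector; degenerate (zero-variance) cases and ties resolve
    uniformly at random (seeded)."""
    tv = test - test.mean()
    denom_t = np.sqrt((tv**2).sum())
    if denom_t == 0:
        return int(rng.integers(0, templates.shape[0]))
    tm = templates - templates.mean(axis=1, keepdims=True)
    denom_m = np.sqrt((tm**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tm @ tv) / (denom_m * denom_t)
    r = np.where(np.isfinite(r), r, -np.inf)
    best = np.flatnonzero(r == r.max())
    return int(best[0] if best.size == 1 else rng.choice(best))


def lda_decode(
    train_X: np.ndarray, train_y: np.ndarray, test: np.ndarray
) -> int:
    """Shrinkage-regularized LDA with a uniform class prior (library-backed)."""
    classes = np.unique(train_y)
    lda = LinearDiscriminantAnalysis(
        solver="lsqr", shrinkage="auto", priors=np.full(classes.size, 1 / classes.size)
    )
    lda.fit(train_X, train_y)
    return int(lda.predict(test[None, :])[0])


def _apply_manipulation(feat: np.ndarray, manipulation: str) -> np.ndarray:
    """feat has shape (..., n_units, n_bins); returns flattened features."""
    if manipulation == "none":
        return feat.reshape(*feat.shape[:-2], -1)
    if manipulation == "avg_time":
        return feat.mean(axis=-1)
    if manipulation == "avg_units":
        return feat.mean(axis=-2)
    raise ValueError(f"unknown manipulation {manipulation!r}")


def decoding_experiment(
    X: np.ndarray,
    unit_types: np.ndarray,
    n_units: int,
    composition: str = "mixture",
    manipulation: str = "none",
    decoder: str = "mcc",
    n_samples: int = 50,
    rng_seed: int = 0,
) -> dict:
    """Repeated pseudopopulation decoding.

    ``X`` is the (unit, stimulus, repetition, bin) count tensor;
    ``unit_types`` gives each unit's label ('RS'/'Bu'/...).  For each of
    ``n_samples`` draws, a pseudopopulation is sampled, per-unit left-out
    test trials selected, class templates built from the remaining
    repetitions, the manipulation applied, and every stimulus's test
    pseudo-trial decoded.  Accuracy is the diagonal mass fraction of the
    pooled confusion matrix.
    """
    n_units_total, n_stim, n_reps, n_bins = X.shape
    if n_units_total == 0:
        raise ValueError("empty pool")
    rng = np.random.default_rng(rng_seed)
    pool = np.arange(n_units_total)
    cm = np.zeros((n_stim, n_stim))
    for _ in range(n_samples):
        chosen, test_idx = sample_pseudopopulation(
            pool, unit_types, n_units, composition, n_reps, n_stim, rng
        )
        sub = X[chosen]  # (n, S, R, B)
        n = chosen.size
        # templates: mean over training (non-left-out) reps, per unit per stim
        templates = np.empty((n_stim, n, n_bins))
        tests = np.empty((n_stim, n, n_bins))
        for ui in range(n):
            for si in range(n_stim):
                ti = test_idx[ui, si]
                tests[si, ui] = sub[ui, si, ti]
                mask = np.ones(n_reps, bool)
                mask[ti] = False
                templates[si, ui] = sub[ui, si, mask].mean(axis=0)
        tfeat = _apply_manipulation(templates, manipulation)
        xfeat = _apply_manipulation(tests, manipulation)
        if decoder == "mcc":
            for si in range(n_stim):
                cm[si, mcc_decode(tfeat, xfeat[si], rng)] += 1
        elif decoder == "lda":
            # R-1 training pseudo-trials per stimulus: slot k pairs each
            # unit's k-th non-left-out repetition
            train_feats, train_y = [], []
            for si in range(n_stim):
                train_reps = np.empty((n, n_reps - 1, n_bins))
                for ui in range(n):
                    mask = np.ones(n_reps, bool)
                    mask[test_idx[ui, si]] = False
                    train_reps[ui] = sub[ui, si, mask]
                for k in range(n_reps - 1):
                    train_feats.append(
                        _apply_manipulation(train_reps[None, :, k, :], manipulation)[0]
                    )
                    train_y.append(si)
            train_X = np.asarray(train_feats)
            train_y = np.asarray(train_y)
            for si in range(n_stim):
                cm[si, lda_decode(train_X, train_y, xfeat[si])] += 1
        else:
            raise ValueError(f"unknown decoder {decoder!r}")
    accuracy = float(np.trace(cm) / cm.sum())
    return {"confusion": cm, "accuracy": accuracy, "n_samples": n_samples}
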