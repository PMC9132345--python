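"""Unit-type assignment: consensus criteria and unsupervised PCA+GMM.

Criteria (evaluated in sequence, bursting first):

* Bursting (Bu): ISI peak < 10 ms AND autocorrelogram metric > 0.5 AND
  logISIdrop > 0.2.  Exactly 2 of 3 -> unclassified; otherwise nonbursting.
* PBu: prestimulus logISIdrop > 0.3 (bursting judged from spontaneous
  activity alone).  A nonbursting unit that is PBu is "bursting_ambiguous"
  and is not considered for RS/FS.
* FS: at least 2 of {t_TTP < 0.5 ms, f50 > 2 kHz, spontaneous > 5 spk/s};
  RS: at least 2 of {t_TTP > 0.5 ms, f50 < 2 kHz, spontaneous < 3 spk/s};
  both or neither -> unclassified.
* Bu1/Bu2 split at 500 Hz intraburst frequency (>500 -> Bu1).

The unsupervised route standardizes 8 features (log-transforming strongly
skewed ones), projects onto 3 principal components, fits a full-covariance
Gaussian mixture (best of 20 seeds by AIC), and assigns a unit to a
component only when its posterior is at least twice each other posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from . import features as ft
from . import responses as rp
from . import waveforms as wf
from .session import UnitRecording, pool_intervals, pool_prestim_intervals

GMM_FEATURES = [
    "acm",
    "isi_peak_ms",
    "log_isi_drop",
    "pct_isi_lt_5ms",
    "spontaneous_rate",
    "f50_hz",
    "max_burst_len",
    "max_firing_rate",
]

BU_SPLIT_HZ = 500.0
SKEW_THRESHOLD = 2.0


@dataclass(frozen=True)
class TypeLabel:
    label: str  # RS | FS | Bu | Bu1 | Bu2 | PBu | unclassified | bursting_ambiguous | nonbursting
    method: str  # criteria | gmm | prestim
    posteriors: dict[str, float] | None = None
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# feature extraction


def unit_feature_row(
    unit: UnitRecording,
    source_protocol: str | None = "tuning",
    source: str = "all",
) -> dict:
    """All classification features for one unit; missing values are NaN.

    With ``source='all'``, ISI/autocorrelogram features use whole trials of
    the standardized tuning protocol when present (falling back to all
    protocols), so spike-timing features come from a comparable recording
    epoch for every unit; with ``source='prestim'`` they use only the pooled
    200 ms prestimulus segments.  The prestimulus burst score always pools
    the prestimulus segments of every protocol.
    """
    from .session import slice_epoch

    row: dict = {"unit_id": unit.unit_id, "truth_type": unit.truth_type}
    proto = source_protocol if source_protocol in unit.protocols else None
    if source == "prestim":
        intervals = pool_prestim_intervals(unit)
        segments = [
            slice_epoch(tr, (-unit.prestim_duration, 0.0)).times for tr in unit.trains
        ]
    elif source == "all":
        intervals = pool_intervals(unit, protocol=proto)
        segments = [
            tr.times for tr in unit.trains if proto is None or tr.protocol == proto
        ]
    else:
        raise ValueError(f"unknown source {source!r}")

    row["n_intervals"] = intervals.size
    for key in (
        "isi_peak_ms",
        "log_isi_drop",
        "intraburst_freq_hz",
        "pct_isi_lt_5ms",
        "max_burst_len",
        "mean_burst_len",
        "pct_normalized",
        "regularity",
        "refractory_ms",
    ):
        row[key] = np.nan
    if intervals.size >= ft.MIN_INTERVALS:
        log_h = ft.isi_histogram(intervals, "log")
        lin_h = ft.isi_histogram(intervals, "linear")
        row["isi_peak_ms"] = ft.isi_peak(log_h)
        row["log_isi_drop"] = ft.log_isi_drop(intervals)
        row["intraburst_freq_hz"] = ft.intraburst_frequency(lin_h)
        bs = ft.burst_stats(intervals, row["isi_peak_ms"])
        row.update(
            {
                "pct_isi_lt_5ms": bs["pct_isi_lt_5ms"],
                "max_burst_len": bs["max_burst_len"],
                "mean_burst_len": bs["mean_burst_len"],
                "pct_normalized": bs["pct_normalized"],
                "regularity": bs["regularity"],
            }
        )
        refr = ft.refractory_period(lin_h)
        row["refractory_ms"] = np.nan if refr is None else refr * 1000.0

    ac = ft.autocorrelogram(segments)
    acm = ft.autocorrelogram_metric(ac)
    row["acm"] = np.nan if acm is None else acm

    prestim_iv = pool_prestim_intervals(unit)
    row["n_prestim_intervals"] = prestim_iv.size
    row["prestim_log_isi_drop"] = (
        ft.log_isi_drop(prestim_iv) if prestim_iv.size >= ft.MIN_INTERVALS else np.nan
    )

    row["spontaneous_rate"] = rp.spontaneous_rate(unit)
    rates = [rp.driven_rate(unit, sid) for sid in unit.stimuli]
    row["max_firing_rate"] = max(rates) if rates else np.nan

    row.update(
        wf.unit_waveform_metrics(
            unit.waveforms, unit.waveform_sample_rate, unit.waveform_spike_times
        )
    )

    tone_ids = sorted(s for s, st in unit.stimuli.items() if st.kind == "tone")
    lat = rp.onset_latency(unit, tone_ids or None)
    row["latency_ms"] = np.nan if lat is None else lat * 1000.0
    return row


def feature_table(units: list[UnitRecording], source: str = "all") -> pd.DataFrame:
    """One feature row per unit, indexed by unit_id."""
    df = pd.DataFrame([unit_feature_row(u, source=source) for u in units])
    return df.set_index("unit_id")


# ---------------------------------------------------------------------------
# criteria classification


def classify_bursting_criteria(fv: dict) -> str:
    """'Bu' (3/3 criteria), 'unclassified' (exactly 2/3) or 'nonbursting'."""
    needed = ("isi_peak_ms", "acm", "log_isi_drop")
    if any(fv.get(k) is None or np.isnan(fv[k]) for k in needed):
        return "unclassifiable"
    hits = sum(
        [fv["isi_peak_ms"] < 10.0, fv["acm"] > 0.5, fv["log_isi_drop"] > 0.2]
    )
    if hits == 3:
        return "Bu"
    if hits == 2:
        return "unclassified"
    return "nonbursting"


def classify_pbu(fv: dict) -> bool | None:
    """Prestimulus-only bursting; None when < 50 prestimulus ISIs."""
    v = fv.get("prestim_log_isi_drop")
    if v is None or np.isnan(v):
        return None
    return bool(v > 0.3)


def classify_rs_fs_criteria(fv: dict) -> str:
    """RS/FS consensus on a *nonbursting* unit; 2 of 3 criteria required."""
    burst = classify_bursting_criteria(fv)
    if burst == "Bu":
        raise ValueError("classify_rs_fs_criteria called on a bursting unit")
    ttp, f50, sp = fv.get("t_ttp_ms"), fv.get("f50_hz"), fv.get("spontaneous_rate")

    def ok(x):
        return x is not None and not np.isnan(x)

    fs_hits = sum([ok(ttp) and ttp < 0.5, ok(f50) and f50 > 2000.0, ok(sp) and sp > 5.0])
    rs_hits = sum([ok(ttp) and ttp > 0.5, ok(f50) and f50 < 2000.0, ok(sp) and sp < 3.0])
    if fs_hits >= 2 and rs_hits >= 2:
        return "unclassified"
    if fs_hits >= 2:
        return "FS"
    if rs_hits >= 2:
        return "RS"
    return "unclassified"


def classify_unit_criteria(fv: dict) -> TypeLabel:
    """Full sequential criteria classification of one feature row."""
    burst = classify_bursting_criteria(fv)
    pbu = classify_pbu(fv)
    detail = {"bursting": burst, "pbu": pbu}
    if burst == "Bu":
        return TypeLabel("Bu", "criteria", detail=detail)
    if burst in ("unclassified", "unclassifiable"):
        return TypeLabel("unclassified", "criteria", detail=detail)
    if pbu:
        return TypeLabel("bursting_ambiguous", "criteria", detail=detail)
    return TypeLabel(classify_rs_fs_criteria(fv), "criteria", detail=detail)


def split_bu_subgroups(
    bu_rows: pd.DataFrame, mode: str = "criterion", rng_seed: int = 0
) -> pd.Series:
    """Bu1/Bu2 labels for bursting units.

    criterion mode thresholds intraburst frequency at 500 Hz (> -> Bu1);
    gmm mode fits a 2-component mixture on (intraburst frequency,
    logISIdrop, latency) and names the higher-intraburst component Bu1.
    """
    if mode == "criterion":
        return pd.Series(
            np.where(bu_rows["intraburst_freq_hz"] > BU_SPLIT_HZ, "Bu1", "Bu2"),
            index=bu_rows.index,
        )
    if mode != "gmm":
        raise ValueError(f"unknown mode {mode!r}")
    cols = ["intraburst_freq_hz", "log_isi_drop", "latency_ms"]
    sub = bu_rows[cols].dropna()
    if len(sub) < 6:
        raise ValueError("gmm Bu split needs at least 6 bursting units")
    X = (sub - sub.mean()) / sub.std(ddof=0)
    gm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=5, random_state=rng_seed
    ).fit(X.to_numpy())
    comp = gm.predict(X.to_numpy())
    mean_if = [sub["intraburst_freq_hz"][comp == k].mean() for k in (0, 1)]
    bu1 = int(np.argmax(mean_if))
    out = pd.Series("Bu2", index=sub.index)
    out[comp == bu1] = "Bu1"
    return out


# ---------------------------------------------------------------------------
# feature matrix + PCA/GMM estimator


def build_feature_matrix(
    df: pd.DataFrame, columns: list[str] = GMM_FEATURES
) -> tuple[np.ndarray, pd.Index, dict]:
    """Standardized complete-case matrix for clustering.

    Columns with |skewness| > 2 are log-transformed first; if such a column
    contains zeros, an offset of half its minimum positive value is added
    before the log.  Every output column has mean 0 and SD 1.  Returns
    (matrix, row index, per-column transform info).
    """
    sub = df[columns].dropna()
    info: dict = {"rows": len(sub), "transforms": {}}
    X = np.empty((len(sub), len(columns)))
    for j, col in enumerate(columns):
        v = sub[col].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            raise ValueError(f"feature {col!r} is constant; cannot standardize")
        g1 = stats.skew(v)
        if abs(g1) > SKEW_THRESHOLD:
            offset = 0.0
            if v.min() <= 0:
                pos = v[v > 0]
                offset = 0.5 * pos.min() if pos.size else 1.0
            v = np.log(v + offset)
            info["transforms"][col] = {"log": True, "offset": offset, "skew": float(g1)}
        else:
            info["transforms"][col] = {"log": False, "skew": float(g1)}
        X[:, j] = (v - v.mean()) / v.std(ddof=0)
    return X, sub.index, info


class GmmTypeClassifier(BaseEstimator):
    """PCA + full-covariance Gaussian mixture unit-type classifier.

    Fits a PCA (3 components) to the standardized feature matrix and, for
    each candidate component count, a full-covariance GMM taking the best
    of ``n_seeds`` random initializations by AIC.  Model-selection curves
    (AIC, BIC and half/half cross-validated negative log-likelihood) are
    exposed as fitted attributes; prediction assigns a unit to a component
    only when its posterior is at least twice each other posterior, and
    components are mapped to RS/FS/Bu by their feature centroids (Bu =
    highest autocorrelogram-metric centroid, FS = highest spontaneous-rate
    centroid among the rest).

    Parameters
    ----------
    n_components : component count used for assignment (3 unit types).
    k_range : candidate counts for the model-selection curves.
    n_seeds : random initializations per candidate count.
    cv_repeats : number of half/half splits for held-out likelihood.
    feature_names : column order of the input matrix (needed for the
        centroid mapping); defaults to the 8 standard features.
    """

    def __init__(
        self,
        n_components: int = 3,
        k_range: tuple = (1, 2, 3, 4, 5, 6, 7),
        n_seeds: int = 20,
        cv_repeats: int = 50,
        n_pca: int = 3,
        feature_names: list[str] | None = None,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.k_range = k_range
        self.n_seeds = n_seeds
        self.cv_repeats = cv_repeats
        self.n_pca = n_pca
        self.feature_names = feature_names
        self.random_state = random_state

    def _best_gmm(self, Z: np.ndarray, k: int, seed0: int) -> GaussianMixture | None:
        best, best_aic = None, np.inf
        for s in range(self.n_seeds):
            gm = GaussianMixture(
                n_components=k, covariance_type="full", random_state=seed0 + s
            )
            try:
                gm.fit(Z)
            except ValueError:
                continue
            if not gm.converged_:
                continue
            aic = gm.aic(Z)
            if aic < best_aic:
                best, best_aic = gm, aic
        return best

    def fit(self, X: np.ndarray, y=None) -> "GmmTypeClassifier":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 10:
            raise ValueError("need at least 10 complete rows")
        names = self.feature_names or GMM_FEATURES
        if X.shape[1] != len(names):
            raise ValueError("feature_names must match the matrix width")
        self.feature_names_ = list(names)
        self.pca_ = PCA(n_components=min(self.n_pca, X.shape[1]), random_state=self.random_state)
        Z = self.pca_.fit_transform(X)
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_

        self.aic_, self.bic_, self.models_ = {}, {}, {}
        for k in self.k_range:
            gm = self._best_gmm(Z, k, self.random_state * 1000 + k)
            if gm is None:
                continue
            self.models_[k] = gm
            self.aic_[k] = float(gm.aic(Z))
            self.bic_[k] = float(gm.bic(Z))

        rng = np.random.default_rng(self.random_state)
        self.cv_nll_ = {k: [] for k in self.models_}
        for _ in range(self.cv_repeats):
            perm = rng.permutation(Z.shape[0])
            half = Z.shape[0] // 2
            tr, te = Z[perm[:half]], Z[perm[half:]]
            for k in self.models_:
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type="full",
                    random_state=int(rng.integers(2**31 - 1)),
                )
                try:
                    gm.fit(tr)
                    self.cv_nll_[k].append(-gm.score(te))
                except ValueError:
                    pass
        self.cv_nll_ = {
            k: float(np.mean(v)) for k, v in self.cv_nll_.items() if len(v)
        }

        if self.n_components not in self.models_:
            raise RuntimeError(f"no converged model with {self.n_components} components")
        self.gmm_ = self.models_[self.n_components]
        self.component_types_ = (
            self._map_components() if self.n_components >= 3 else None
        )
        return self

    def _map_components(self) -> list[str]:
        # component centroids back in (standardized) feature space
        cent = self.pca_.inverse_transform(self.gmm_.means_)
        names = self.feature_names_
        acm_j = names.index("acm")
        sp_j = names.index("spontaneous_rate")
        order = np.argsort(-cent[:, acm_j])
        if self.gmm_.n_components < 3:
            raise ValueError("component mapping requires >= 3 components")
        if np.isclose(cent[order[0], acm_j], cent[order[1], acm_j]):
            raise ValueError("ambiguous centroid mapping (tied ACM centroids)")
        types = [""] * self.gmm_.n_components
        bu = order[0]
        types[bu] = "Bu"
        rest = [i for i in range(self.gmm_.n_components) if i != bu]
        fs = rest[int(np.argmax(cent[rest, sp_j]))]
        types[fs] = "FS"
        for i in rest:
            if i != fs:
                types[i] = "RS"
        return types

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "gmm_")
        return self.gmm_.predict_proba(self.pca_.transform(np.asarray(X, float)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Type labels; 'unclassified' when the 2x posterior rule fails."""
        post = self.predict_proba(X)
        labels = []
        for p in post:
            order = np.argsort(-p)
            if p[order[0]] >= 2.0 * p[order[1]] - 1e-12:
                labels.append(self.component_types_[order[0]])
            else:
                labels.append("unclassified")
        return np.asarray(labels)


# ---------------------------------------------------------------------------
# method agreement


def agreement_matrix(
    labels_a: pd.Series, labels_b: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Confusion matrix and agreement fraction over units *labeled by both*
    methods (Bu1/Bu2 collapse to Bu; unclassified/ambiguous rows drop)."""

    def canon(s: pd.Series) -> pd.Series:
        s = s.replace({"Bu1": "Bu", "Bu2": "Bu"})
        return s[s.isin(["RS", "FS", "Bu"])]

    a, b = canon(labels_a), canon(labels_b)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no units labeled by both methods")
    a, b = a.loc[common], b.loc[common]
    cm = pd.crosstab(a, b, dropna=False)
    agreement = float((a == b).mean())
    return cm, agreement


def classify_units(
    df: pd.DataFrame, method: str = "both", rng_seed: int = 0
) -> pd.DataFrame:
    """Criteria and/or GMM labels for a feature table; returns a copy of the
    table with ``label_criteria`` / ``label_gmm`` (and Bu subgroup) columns."""
    out = df.copy()
    if method in ("criteria", "both"):
        labels = [classify_unit_criteria(row._asdict() if hasattr(row, "_asdict") else dict(row))
                  for _, row in df.iterrows()]
        out["label_criteria"] = [l.label for l in labels]
        bu = out[out["label_criteria"] == "Bu"]
        if len(bu):
            sub = split_bu_subgroups(bu, "criterion")
            out.loc[sub.index, "label_criteria_sub"] = sub
    if method in ("gmm", "both"):
        X, idx, _ = build_feature_matrix(df)
        clf = GmmTypeClassifier(random_state=rng_seed).fit(X)
        out["label_gmm"] = pd.Series(clf.predict(X), index=idx)
    return out
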