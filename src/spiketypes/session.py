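"""Data model and on-disk format for unit recordings.

Spike times are stored in seconds, aligned so that stimulus onset is at
t = 0; a trial span therefore covers ``[-prestim, duration + posttrial]``.
All windows are half-open ``[t0, t1)`` so that spike counts are conserved
exactly under any partition of a trial.

A *session* on disk is a directory with::

    manifest.json   -- unit list, prestim duration, file names
    spikes.csv      -- unit_id, protocol, stimulus_id, repetition, time_s
    stimuli.csv     -- stimulus_id, kind, onset_s, duration_s, mod_rate_hz, ramp_s
    waveforms.h5    -- per-unit dataset (n_spikes x n_samples), attrs sample_rate_hz

Times are quantized to 1 microsecond on write (finer than the ~41 us sample
period of the recordings), which makes read(write(x)) an exact round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

STIMULUS_KINDS = ("tone", "bandpass", "SAM", "duration_series", "ramp", "vocalization")

_TIME_DECIMALS = 6  # 1 us quantization on write


class SessionFormatError(ValueError):
    """Malformed manifest or inconsistent session files."""


@dataclass(frozen=True)
class StimulusDescriptor:
    """One stimulus: identity, envelope kind and timing metadata."""

    stimulus_id: str
    kind: str
    duration: float
    onset: float = 0.0
    mod_rate: float | None = None  # Hz, SAM only
    ramp_time: float | None = None  # s, ramp only
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in STIMULUS_KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if not self.duration > 0:
            raise ValueError("stimulus duration must be > 0")
        if self.onset < 0:
            raise ValueError("stimulus onset must be >= 0")
        if self.kind == "SAM" and not (self.mod_rate and self.mod_rate > 0):
            raise ValueError("SAM stimulus requires mod_rate > 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (s) of one trial, aligned to stimulus onset at t = 0."""

    times: np.ndarray
    trial_span: tuple[float, float]
    stimulus_id: str
    repetition: int = 0
    protocol: str = "default"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-d array")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        t0, t1 = self.trial_span
        if t.size and (t[0] < t0 or t[-1] > t1):
            raise ValueError("spike times outside trial span")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class UnitRecording:
    """All trials, stimuli and waveform snippets of one recorded unit."""

    unit_id: str
    trains: list[SpikeTrain]
    stimuli: dict[str, StimulusDescriptor]
    waveforms: np.ndarray | None = None  # (n_spikes, n_samples)
    waveform_sample_rate: float = 24414.0
    waveform_spike_times: np.ndarray | None = None  # s, for isolation checks
    prestim_duration: float = 0.200
    truth_type: str | None = None

    def __post_init__(self):
        if self.waveform_sample_rate <= 0:
            raise ValueError("waveform sample rate must be > 0")
        for tr in self.trains:
            if tr.stimulus_id not in self.stimuli:
                raise SessionFormatError(
                    f"unit {self.unit_id}: train references unknown stimulus_id "
                    f"{tr.stimulus_id!r}"
                )

    def trains_for(self, stimulus_id: str, protocol: str | None = None) -> list[SpikeTrain]:
        out = [t for t in self.trains if t.stimulus_id == stimulus_id]
        if protocol is not None:
            out = [t for t in out if t.protocol == protocol]
        return sorted(out, key=lambda t: t.repetition)

    @property
    def protocols(self) -> list[str]:
        return sorted({t.protocol for t in self.trains})


def slice_epoch(train: SpikeTrain, window: tuple[float, float]) -> SpikeTrain:
    """Restrict a train to the half-open window ``[t0, t1)``.

    A window outside the trial span yields an empty train rather than an
    error; spike counts are conserved under any partition of the span.
    """
    t0, t1 = window
    if not t0 < t1:
        if t0 == t1:
            return replace(train, times=np.empty(0), trial_span=(t0, t1))
        raise ValueError("window must satisfy t0 < t1")
    t = train.times
    sel = t[(t >= t0) & (t < t1)]
    return replace(train, times=sel, trial_span=(t0, t1))


def pool_prestim_intervals(unit: UnitRecording) -> np.ndarray:
    """ISIs (s) from the prestimulus epochs of every trial, pooled.

    Each trial contributes the intervals between consecutive spikes that
    fall inside its own prestimulus segment ``[-prestim, 0)``; intervals are
    never taken across segment boundaries.  Pooling runs over all stimuli,
    repetitions and protocols of the unit.
    """
    isis = []
    for tr in unit.trains:
        seg = slice_epoch(tr, (-unit.prestim_duration, 0.0)).times
        if seg.size >= 2:
            isis.append(np.diff(seg))
    if not isis:
        return np.empty(0)
    return np.concatenate(isis)


def pool_intervals(unit: UnitRecording, protocol: str | None = None) -> np.ndarray:
    """ISIs (s) within whole trials (stimulated + unstimulated periods)."""
    isis = []
    for tr in unit.trains:
        if protocol is not None and tr.protocol != protocol:
            continue
        if tr.n_spikes >= 2:
            isis.append(np.diff(tr.times))
    if not isis:
        return np.empty(0)
    return np.concatenate(isis)


# ---------------------------------------------------------------------------
# readers / writers


def write_session(units: list[UnitRecording], out_dir: str | Path) -> Path:
    """Write a session directory; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spike_rows = []
    stim_rows = {}
    unit_meta = []
    have_waveforms = False
    for u in sorted(units, key=lambda u: u.unit_id):
        for sid, st in u.stimuli.items():
            stim_rows[sid] = {
                "stimulus_id": sid,
                "kind": st.kind,
                "onset_s": st.onset,
                "duration_s": st.duration,
                "mod_rate_hz": "" if st.mod_rate is None else st.mod_rate,
                "ramp_s": "" if st.ramp_time is None else st.ramp_time,
            }
        for tr in u.trains:
            for t in np.round(tr.times, _TIME_DECIMALS):
                spike_rows.append(
                    {
                        "unit_id": u.unit_id,
                        "protocol": tr.protocol,
                        "stimulus_id": tr.stimulus_id,
                        "repetition": tr.repetition,
                        "time_s": f"{t:.6f}",
                    }
                )
        spans = {
            (tr.protocol, tr.stimulus_id, tr.repetition): tr.trial_span for tr in u.trains
        }
        unit_meta.append(
            {
                "unit_id": u.unit_id,
                "prestim_duration": u.prestim_duration,
                "truth_type": u.truth_type,
                "trial_spans": [
                    {
                        "protocol": k[0],
                        "stimulus_id": k[1],
                        "repetition": k[2],
                        "span": [round(v[0], _TIME_DECIMALS), round(v[1], _TIME_DECIMALS)],
                    }
                    for k, v in sorted(spans.items())
                ],
            }
        )
        if u.waveforms is not None and len(u.waveforms):
            have_waveforms = True

    pd.DataFrame(
        spike_rows,
        columns=["unit_id", "protocol", "stimulus_id", "repetition", "time_s"],
    ).to_csv(out / "spikes.csv", index=False)
    pd.DataFrame(
        sorted(stim_rows.values(), key=lambda r: r["stimulus_id"]),
        columns=["stimulus_id", "kind", "onset_s", "duration_s", "mod_rate_hz", "ramp_s"],
    ).to_csv(out / "stimuli.csv", index=False)

    if have_waveforms:
        import h5py

        with h5py.File(out / "waveforms.h5", "w") as f:
            for u in sorted(units, key=lambda u: u.unit_id):
                if u.waveforms is None or not len(u.waveforms):
                    continue
                g = f.create_group(u.unit_id)
                d = g.create_dataset("snippets", data=np.asarray(u.waveforms, dtype=np.float32))
                d.attrs["sample_rate_hz"] = float(u.waveform_sample_rate)
                if u.waveform_spike_times is not None:
                    g.create_dataset(
                        "spike_times_s", data=np.asarray(u.waveform_spike_times, float)
                    )

    manifest = {
        "format": "spiketypes-session",
        "version": 1,
        "spikes": "spikes.csv",
        "stimuli": "stimuli.csv",
        "waveforms": "waveforms.h5" if have_waveforms else None,
        "units": unit_meta,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def read_session(manifest_path: str | Path) -> list[UnitRecording]:
    """Read a session directory written by :func:`write_session`.

    Missing waveform files yield recordings with an empty waveform block;
    a train referencing an unknown stimulus raises :class:`SessionFormatError`.
    """
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as e:
        raise SessionFormatError(f"malformed manifest {manifest_path}: {e}") from e
    for key in ("spikes", "stimuli", "units"):
        if key not in manifest:
            raise SessionFormatError(f"manifest {manifest_path} missing field {key!r}")
    base = manifest_path.parent

    stim_df = pd.read_csv(base / manifest["stimuli"], dtype={"stimulus_id": str})
    stimuli = {}
    for _, r in stim_df.iterrows():
        stimuli[r["stimulus_id"]] = StimulusDescriptor(
            stimulus_id=r["stimulus_id"],
            kind=r["kind"],
            onset=float(r["onset_s"]),
            duration=float(r["duration_s"]),
            mod_rate=None if pd.isna(r["mod_rate_hz"]) else float(r["mod_rate_hz"]),
            ramp_time=None if pd.isna(r["ramp_s"]) else float(r["ramp_s"]),
        )

    spike_df = pd.read_csv(
        base / manifest["spikes"], dtype={"unit_id": str, "stimulus_id": str}
    )

    wf_path = base / manifest["waveforms"] if manifest.get("waveforms") else None
    wf_file = None
    if wf_path is not None and wf_path.exists():
        import h5py

        wf_file = h5py.File(wf_path, "r")

    units = []
    try:
        for meta in manifest["units"]:
            uid = str(meta["unit_id"])
            spans = {
                (s["protocol"], str(s["stimulus_id"]), int(s["repetition"])): tuple(s["span"])
                for s in meta["trial_spans"]
            }
            sub = spike_df[spike_df["unit_id"] == uid]
            grouped = {
                key: np.sort(g["time_s"].to_numpy(float))
                for key, g in sub.groupby(["protocol", "stimulus_id", "repetition"], sort=True)
            }
            trains = []
            for key, span in sorted(spans.items()):
                proto, sid, rep = key
                if sid not in stimuli:
                    raise SessionFormatError(
                        f"unit {uid}: train references unknown stimulus_id {sid!r}"
                    )
                times = grouped.get((proto, sid, int(rep)), np.empty(0))
                trains.append(
                    SpikeTrain(
                        times=times,
                        trial_span=span,
                        stimulus_id=sid,
                        repetition=int(rep),
                        protocol=proto,
                    )
                )
            used_stims = {t.stimulus_id for t in trains}
            waveforms = None
            sample_rate = 24414.0
            wf_times = None
            if wf_file is not None and uid in wf_file:
                g = wf_file[uid]
                waveforms = np.asarray(g["snippets"], dtype=float)
                sample_rate = float(g["snippets"].attrs["sample_rate_hz"])
                if "spike_times_s" in g:
                    wf_times = np.asarray(g["spike_times_s"], dtype=float)
            units.append(
                UnitRecording(
                    unit_id=uid,
                    trains=trains,
                    stimuli={k: v for k, v in stimuli.items() if k in used_stims},
                    waveforms=waveforms,
                    waveform_sample_rate=sample_rate,
                    waveform_spike_times=wf_times,
                    prestim_duration=float(meta.get("prestim_duration", 0.200)),
                    truth_type=meta.get("truth_type"),
                )
            )
    finally:
        if wf_file is not None:
            wf_file.close()
    return units
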