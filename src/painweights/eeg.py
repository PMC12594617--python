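"""Event-locked windowing and P2 peak extraction from epoched EEG-like data.

Epochs are stimulation-locked (spanning -4500 to +500 ms at 500 Hz by
default) and carry per-trial event markers: ``pair_onset`` (the two cue
pairs appear), ``choice``, ``cue_onset`` (the chosen cue is displayed for
3 s) and ``stim_onset``. Four canonical analysis windows are anchored on
those markers:

* baseline            [-500, 0) ms from pair_onset (fixation cross)
* early_anticipation  [0, 500) ms from cue_onset
* late_anticipation   [2500, 3000) ms from cue_onset (= last 500 ms before
  stimulation under the 3 s cue display)
* post_stimulation    P2 peak +/- 100 ms from stim_onset, defined per
  participant after peak detection

All windows are half-open ``[start, end)`` at sample resolution;
millisecond offsets round toward the earlier sample. Baseline correction
subtracts the per-trial, per-channel baseline-window mean. The P2 peak is
the maximum of the signed amplitude in the 500 ms post-stimulus (P2 is a
positive deflection); an absolute-value variant is selectable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EpochSet",
    "WindowDef",
    "P2Feature",
    "ERP",
    "window_mean",
    "canonical_windows",
    "participant_erp",
    "select_p2_electrode",
    "detect_p2",
    "save_epochs",
    "load_epochs",
]

EVENT_NAMES = ("pair_onset", "choice", "cue_onset", "stim_onset")


@dataclass
class EpochSet:
    """Trials x channels x samples array with per-trial event markers."""

    data: np.ndarray
    srate: float
    channels: list[str]
    events: dict[str, np.ndarray]  # event name -> per-trial sample index
    participant_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_trials, n_ch, n_samp = self.data.shape
        if n_ch != len(self.channels):
            raise ValueError("channel label count does not match data")
        for name, idx in self.events.items():
            idx = np.asarray(idx, dtype=int)
            if idx.shape != (n_trials,):
                raise ValueError(f"event '{name}' must give one marker per trial")
            if np.any(idx < 0) or np.any(idx >= n_samp):
                raise ValueError(f"event '{name}' markers outside the epoch")
            self.events[name] = idx

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class WindowDef:
    """Half-open window [start_ms, end_ms) relative to an anchor event."""

    anchor: str
    start_ms: float
    end_ms: float
    label: str

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("window end must exceed start")


@dataclass(frozen=True)
class P2Feature:
    """Individual P2 peak: electrode, latency, amplitude, +/-100 ms window."""

    electrode: str
    latency_ms: float
    amplitude: float
    window_ms: tuple[float, float]
    clipped: bool = False


@dataclass
class ERP:
    """Trial-averaged, baseline-corrected potential around stimulation."""

    data: np.ndarray  # channels x samples
    times_ms: np.ndarray
    channels: list[str]


def _ms_to_samples(ms: float, srate: float) -> int:
    # round toward the earlier sample (floor) for a fixed convention
    return int(np.floor(ms * srate / 1000.0))


def _resolve(
    win: WindowDef, epochs: EpochSet, trial: int
) -> tuple[int, int]:
    if win.anchor not in epochs.events:
        raise ValueError(f"missing event marker '{win.anchor}'")
    anchor = int(epochs.events[win.anchor][trial])
    lo = anchor + _ms_to_samples(win.start_ms, epochs.srate)
    hi = anchor + _ms_to_samples(win.end_ms, epochs.srate)
    if lo < 0 or hi > epochs.n_samples:
        raise ValueError(
            f"window '{win.label}' [{win.start_ms}, {win.end_ms}) ms "
            f"falls outside the epoch on trial {trial}"
        )
    return lo, hi


def window_mean(
    epochs: EpochSet, win: WindowDef, baseline: WindowDef
) -> np.ndarray:
    """Trial-averaged, baseline-corrected mean activity per channel.

    Per trial and channel the baseline-window mean is subtracted before the
    target window is averaged; the result is then averaged over trials.
    """
    out = np.zeros((epochs.n_trials, len(epochs.channels)))
    for t in range(epochs.n_trials):
        b_lo, b_hi = _resolve(baseline, epochs, t)
        w_lo, w_hi = _resolve(win, epochs, t)
        base = epochs.data[t, :, b_lo:b_hi].mean(axis=1)
        out[t] = epochs.data[t, :, w_lo:w_hi].mean(axis=1) - base
    return out.mean(axis=0)


def canonical_windows(
    epochs: EpochSet, p2: Optional[P2Feature] = None
) -> dict[str, WindowDef]:
    """The four analysis windows anchored on the per-trial event markers.

    The post-stimulation window needs the participant's P2 peak; until one
    is supplied only the first three are returned.
    """
    for name in ("pair_onset", "cue_onset", "stim_onset"):
        if name not in epochs.events:
            raise ValueError(f"missing event marker '{name}'")
    wins = {
        "baseline": WindowDef("pair_onset", -500.0, 0.0, "baseline"),
        "early_anticipation": WindowDef(
            "cue_onset", 0.0, 500.0, "early_anticipation"
        ),
        "late_anticipation": WindowDef(
            "cue_onset", 2500.0, 3000.0, "late_anticipation"
        ),
    }
    # validate resolvability on every trial now rather than at use time
    for w in wins.values():
        for t in range(epochs.n_trials):
            _resolve(w, epochs, t)
    if p2 is not None:
        wins["post_stimulation"] = WindowDef(
            "stim_onset", p2.window_ms[0], p2.window_ms[1], "post_stimulation"
        )
    return wins


def participant_erp(
    epochs: EpochSet, pre_ms: float = 500.0, post_ms: float = 500.0
) -> ERP:
    """Stimulation-locked ERP over [-pre, +post) ms.

    Each trial is baseline-corrected with its [-pre, 0) ms pre-stimulus mean
    per channel, then trials are averaged.
    """
    if epochs.n_trials == 0:
        raise ValueError("participant_erp requires at least one trial")
    n_pre = _ms_to_samples(pre_ms, epochs.srate)
    n_post = _ms_to_samples(post_ms, epochs.srate)
    segs = np.zeros((epochs.n_trials, len(epochs.channels), n_pre + n_post))
    for t in range(epochs.n_trials):
        s = int(epochs.events["stim_onset"][t])
        if s - n_pre < 0 or s + n_post > epochs.n_samples:
            raise ValueError(f"ERP window outside the epoch on trial {t}")
        seg = epochs.data[t, :, s - n_pre : s + n_post]
        base = seg[:, :n_pre].mean(axis=1, keepdims=True)
        segs[t] = seg - base
    times = (np.arange(n_pre + n_post) - n_pre) / epochs.srate * 1000.0
    return ERP(data=segs.mean(axis=0), times_ms=times, channels=list(epochs.channels))


def select_p2_electrode(erps: Sequence[ERP]) -> str:
    """Electrode with the highest grand-average P2 amplitude.

    ERPs are averaged across participants; per channel the maximum amplitude
    in the post-stimulus interval (t > 0) is taken and the argmax channel
    returned. Ties resolve to the first channel in label order, with a
    warning.
    """
    if not erps:
        raise ValueError("no ERPs supplied")
    ref = erps[0]
    for e in erps[1:]:
        if e.channels != ref.channels or e.data.shape != ref.data.shape:
            raise ValueError("ERPs must share channels and sampling")
    grand = np.mean([e.data for e in erps], axis=0)
    post = ref.times_ms > 0
    peaks = grand[:, post].max(axis=1)
    best = int(np.argmax(peaks))
    ties = np.flatnonzero(peaks == peaks[best])
    if ties.size > 1:
        warnings.warn(
            f"P2 electrode tie between {[ref.channels[i] for i in ties]}; "
            f"keeping '{ref.channels[best]}'",
            stacklevel=2,
        )
    return ref.channels[best]


def detect_p2(
    erp: ERP, electrode: str, mode: str = "signed", max_ms: float = 500.0
) -> P2Feature:
    """Individual P2 peak on the chosen electrode.

    The peak is the point of highest amplitude after stimulation — signed
    amplitude by default (P2 is a positivity), absolute value via
    ``mode="abs"``. The feature window is latency +/- 100 ms, clipped at the
    epoch end (flagged).
    """
    if electrode not in erp.channels:
        raise ValueError(f"electrode '{electrode}' not present")
    if mode not in ("signed", "abs"):
        raise ValueError("mode must be 'signed' or 'abs'")
    sig = erp.data[erp.channels.index(electrode)]
    if not np.all(np.isfinite(sig)):
        raise ValueError("non-finite samples in ERP")
    post = (erp.times_ms > 0) & (erp.times_ms <= max_ms)
    if not np.any(post):
        raise ValueError("no post-stimulus samples")
    crit = np.abs(sig) if mode == "abs" else sig
    idx = np.flatnonzero(post)[np.argmax(crit[post])]
    latency = float(erp.times_ms[idx])
    end = latency + 100.0
    clipped = end > max_ms
    return P2Feature(
        electrode=electrode,
        latency_ms=latency,
        amplitude=float(sig[idx]),
        window_ms=(latency - 100.0, min(end, max_ms)),
        clipped=clipped,
    )


# -- persistence: array file + JSON sidecar -----------------------------------

def save_epochs(epochs: EpochSet, directory: str | Path) -> Path:
    """Write an EpochSet as `<pid>.npy` plus a `<pid>.json` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pid = epochs.participant_id or "participant"
    np.save(directory / f"{pid}.npy", epochs.data)
    sidecar = {
        "participant_id": pid,
        "srate": epochs.srate,
        "channels": epochs.channels,
        "events": {k: v.tolist() for k, v in epochs.events.items()},
        "units": "uV",
    }
    (directory / f"{pid}.json").write_text(json.dumps(sidecar))
    return directory / f"{pid}.npy"


def load_epochs(directory: str | Path, participant_id: str) -> EpochSet:
    directory = Path(directory)
    data = np.load(directory / f"{participant_id}.npy")
    meta = json.loads((directory / f"{participant_id}.json").read_text())
    return EpochSet(
        data=data,
        srate=meta["srate"],
        channels=meta["channels"],
        events={k: np.asarray(v, dtype=int) for k, v in meta["events"].items()},
        participant_id=meta["participant_id"],
    )
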