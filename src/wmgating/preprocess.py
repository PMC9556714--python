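"""Epoch container and the EEG signal-conditioning chain.

The chain mirrors a standard stimulus-locked ERP pipeline: zero-phase
band-pass filtering of the continuous record, anti-aliased resampling,
average re-referencing, automatic amplitude-based artifact rejection,
pre-stimulus baseline correction, and selection of correct response
trials into the four task conditions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

#: The four reference-back task conditions (frame x transition).
CONDITIONS = (
    "switch_reference",
    "nonswitch_reference",
    "switch_comparison",
    "nonswitch_comparison",
)


@dataclass
class EpochSet:
    """Stimulus-locked epochs for one subject.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Epoched EEG in microvolts.
    fs : float
        Sampling rate in Hz.
    times : ndarray, shape (n_samples,)
        Sample times in ms relative to stimulus onset (uniform grid).
    condition : ndarray of str, shape (n_trials,)
        Per-trial condition label (one of :data:`CONDITIONS`, or "" for
        trials not assigned to a condition, e.g. block-initial reference
        trials).
    channel_labels : list of str
    subject : str
    kept_mask : ndarray of bool, shape (n_trials,)
        Trials surviving artifact rejection.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    condition: np.ndarray
    channel_labels: list = field(default_factory=list)
    subject: str = "S00"
    kept_mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.times) != self.data.shape[2]:
            raise ValueError("times length must match sample axis")
        if len(self.condition) != self.data.shape[0]:
            raise ValueError("condition length must match trial axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")
        step = 1000.0 / self.fs
        if len(self.times) > 1 and not np.allclose(
            np.diff(self.times), step, rtol=0, atol=1e-6 * step
        ):
            raise ValueError("times must be a uniform grid with step 1000/fs")
        if not self.channel_labels:
            self.channel_labels = [f"Ch{i + 1}" for i in range(self.data.shape[1])]
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Return a copy restricted to trials where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return EpochSet(
            data=self.data[mask],
            fs=self.fs,
            times=self.times.copy(),
            condition=self.condition[mask],
            channel_labels=list(self.channel_labels),
            subject=self.subject,
            kept_mask=self.kept_mask[mask],
        )

    # -- container I/O: HDF5 array file + JSON sidecar ------------------
    def save(self, path) -> None:
        """Write epochs to ``path`` (HDF5: /data, /times, /labels) plus a
        JSON sidecar ``path + '.json'`` carrying fs, subject and channels."""
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.create_dataset(
                "labels", data=np.array([str(c) for c in self.condition], dtype="S")
            )
            f.create_dataset("kept", data=self.kept_mask.astype(np.uint8))
        sidecar = {
            "fs": self.fs,
            "subject": self.subject,
            "channel_labels": list(self.channel_labels),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "EpochSet":
        import h5py

        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            times = f["times"][()]
            labels = np.array([s.decode() for s in f["labels"][()]], dtype=object)
            kept = f["kept"][()].astype(bool)
        return cls(
            data=data,
            fs=meta["fs"],
            times=times,
            condition=labels,
            channel_labels=meta["channel_labels"],
            subject=meta["subject"],
            kept_mask=kept,
        )


def bandpass_filter(
    raw: np.ndarray, fs: float, hp: float = 0.5, lp: float = 40.0
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a continuous record.

    An 8th-order Butterworth (48 dB/oct per edge and pass) applied
    forward-backward with :func:`scipy.signal.sosfiltfilt`. Works on the
    last axis; accepts (channels, samples) or any leading shape.
    """
    if lp >= fs / 2:
        raise ValueError(f"low-pass {lp} Hz must be below Nyquist {fs / 2} Hz")
    if hp >= lp:
        raise ValueError("high-pass edge must lie below the low-pass edge")
    sos = signal.butter(8, [hp, lp], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(raw, dtype=float), axis=-1)


def resample(x: np.ndarray, fs_in: float = 500.0, fs_out: float = 256.0) -> np.ndarray:
    """Anti-aliased polyphase resampling along the last axis."""
    if fs_out > fs_in:
        raise ValueError("fs_out must not exceed fs_in")
    if fs_out == fs_in:
        return np.asarray(x, dtype=float).copy()
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return signal.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator, axis=-1)


def average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference every sample to the instantaneous channel mean."""
    if epochs.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return replace(epochs, data=data)


def reject_artifacts(
    epochs: EpochSet,
    max_ptp: float = 200.0,
    ptp_window_ms: float = 200.0,
    abs_limit: float = 200.0,
    min_activity: float = 0.5,
    activity_window_ms: float = 100.0,
) -> EpochSet:
    """Automatic amplitude-criteria rejection; updates ``kept_mask``.

    A trial is kept iff on every channel: (a) the peak-to-peak range
    inside every sliding ``ptp_window_ms`` window stays below ``max_ptp``
    microvolts, (b) every sample lies within +-``abs_limit`` microvolts,
    and (c) every sliding ``activity_window_ms`` window shows a
    peak-to-peak range above ``min_activity`` microvolts (flat channels
    indicate a dead recording). Windows advance sample by sample.
    """
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    epoch_ms = (len(epochs.times) - 1) * 1000.0 / epochs.fs
    if epoch_ms < ptp_window_ms:
        raise ValueError("epoch shorter than the peak-to-peak criterion window")
    w_ptp = max(2, int(round(ptp_window_ms / 1000.0 * epochs.fs)))
    w_act = max(2, int(round(activity_window_ms / 1000.0 * epochs.fs)))

    def window_ptp(x: np.ndarray, w: int) -> np.ndarray:
        # peak-to-peak of every complete sliding window, evaluated at the
        # centers where the window fits inside the epoch
        mx = maximum_filter1d(x, size=w, axis=-1)
        mn = minimum_filter1d(x, size=w, axis=-1)
        lo, hi = (w - 1) // 2, x.shape[-1] - 1 - w // 2
        return (mx - mn)[..., lo : hi + 1]

    data = epochs.data
    ok_abs = np.abs(data).max(axis=(1, 2)) <= abs_limit
    ok_ptp = window_ptp(data, w_ptp).max(axis=(1, 2)) < max_ptp
    ok_act = window_ptp(data, w_act).min(axis=(1, 2)) > min_activity
    kept = ok_abs & ok_ptp & ok_act
    if not kept.any():
        warnings.warn("artifact rejection removed every trial", stacklevel=2)
    return replace(epochs, kept_mask=kept & epochs.kept_mask)


def baseline_correct(epochs: EpochSet, window: tuple = (-200.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    lo, hi = window
    if lo < epochs.times[0] or hi > epochs.times[-1]:
        raise ValueError("baseline window lies outside the epoch")
    sel = (epochs.times >= lo) & (epochs.times <= hi)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def select_correct_trials(
    epochs: EpochSet, behavior: pd.DataFrame, rt_limit_ms: float = 1500.0
) -> EpochSet:
    """Keep artifact-free trials with a correct response within the limit.

    ``behavior`` must have one row per trial of ``epochs`` with columns
    ``rt_ms`` (NaN for no-response trials), ``correct`` and ``condition``.
    """
    if len(behavior) != epochs.n_trials:
        raise ValueError(
            f"behavior rows ({len(behavior)}) do not match trials ({epochs.n_trials})"
        )
    rt = behavior["rt_ms"].to_numpy(dtype=float)
    correct = behavior["correct"].to_numpy()
    correct = np.array([bool(c) if not pd.isna(c) else False for c in correct])
    responded = np.isfinite(rt) & (rt <= rt_limit_ms)
    mask = epochs.kept_mask & correct & responded
    out = epochs.select(mask)
    out.condition = np.asarray(
        behavior.loc[mask, "condition"].to_numpy(), dtype=object
    )
    if out.n_trials == 0:
        warnings.warn("no trials survive correct-response selection", stacklevel=2)
    return out


def flag_low_trial_subjects(
    counts: pd.DataFrame, min_trials: int = 50
) -> list:
    """Flag subjects with fewer than ``min_trials`` surviving trials in
    any condition (subject-level exclusion rule).

    ``counts`` is indexed by subject with one column per condition.
    """
    flagged = []
    for subj, row in counts.iterrows():
        if (row.reindex(list(CONDITIONS)).fillna(0) < min_trials).any():
            flagged.append(subj)
    return flagged
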