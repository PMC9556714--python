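"""Synthetic reference-back sessions and forward-model EEG epochs.

The generator emulates the reference-back working-memory gating task:
letters (X/O) inside red (reference, update WM) or blue (comparison,
compare only) frames, 16 blocks of 60 trials, 25% switch transitions,
each block opened by a no-response reference trial. Behavior is drawn
from condition-specific RT/accuracy distributions with the observed
gating costs as defaults; EEG epochs are built by mixing planted,
condition-specific source waveforms through fixed channel topographies
plus spatially correlated Gaussian noise, so every downstream stage of
the cascade has ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .preprocess import CONDITIONS, EpochSet

FRAMES = ("reference", "comparison")

#: Default per-condition mean RTs (ms). Gate-opening RT cost 22.80 ms and
#: gate-closing cost 74.16 ms on top of realistic condition baselines.
DEFAULT_RT_MEANS = {
    "nonswitch_reference": 700.0,
    "switch_reference": 722.80,
    "nonswitch_comparison": 650.0,
    "switch_comparison": 724.16,
}

#: Default per-condition accuracy; opening accuracy cost -3.17 percentage
#: points, closing cost +0.61.
DEFAULT_ACC_PROBS = {
    "nonswitch_reference": 0.95,
    "switch_reference": 0.9183,
    "nonswitch_comparison": 0.95,
    "switch_comparison": 0.9561,
}


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class PlantedSource:
    """A ground-truth EEG source: fixed topography, per-condition waveform.

    ``waveform_by_condition`` maps each condition label to a callable
    evaluating the source amplitude (microvolts) on a time grid in ms.
    """

    topography: np.ndarray
    waveform_by_condition: Dict[str, Callable[[np.ndarray], np.ndarray]]
    trial_jitter_sd: float = 0.0
    label: str = "source"

    def __post_init__(self):
        self.topography = np.asarray(self.topography, dtype=float)
        if np.linalg.norm(self.topography) == 0:
            raise InvalidConfigError(f"source {self.label}: zero topography")


@dataclass
class TrialRecord:
    block: int
    position_in_block: int
    frame: str
    switch: bool
    letter: str
    requires_response: bool
    rt: Optional[float] = None
    correct: Optional[bool] = None

    @property
    def condition(self) -> Optional[str]:
        if not self.requires_response:
            return None
        return f"{'switch' if self.switch else 'nonswitch'}_{self.frame}"


@dataclass
class SimConfig:
    n_subjects: int = 33
    n_channels: int = 60
    fs: float = 256.0
    epoch_window: Tuple[float, float] = (-2000.0, 2000.0)
    n_blocks: int = 16
    trials_per_block: int = 60
    p_switch: float = 0.25
    sources: List[PlantedSource] = field(default_factory=list)
    noise_sd: float = 5.0
    rt_means: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RT_MEANS))
    rt_sd: float = 150.0
    subject_rt_sd: float = 50.0
    # between-subject spread of the gating costs themselves, reproducing
    # the reported cost standard deviations (~32 / ~40 ms) on top of
    # trial-level RT noise
    opening_cost_sd: float = 27.0
    closing_cost_sd: float = 37.0
    acc_probs: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ACC_PROBS))
    rt_deadline: float = 1400.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.p_switch < 1.0:
            raise InvalidConfigError("p_switch must lie strictly in (0, 1)")
        if self.fs <= 0:
            raise InvalidConfigError("fs must be positive")
        lo, hi = self.epoch_window
        if not lo < 0.0 < hi:
            raise InvalidConfigError("epoch window must span stimulus onset")
        if self.trials_per_block < 2:
            raise InvalidConfigError("trials_per_block must be at least 2")
        for probs in (self.acc_probs,):
            for cond, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise InvalidConfigError(f"acc_probs[{cond}] outside [0, 1]")

    @property
    def epoch_times(self) -> np.ndarray:
        lo, hi = self.epoch_window
        n = int(round((hi - lo) / 1000.0 * self.fs)) + 1
        return lo + np.arange(n) * (1000.0 / self.fs)


def generate_trial_sequence(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> List[TrialRecord]:
    """Build one session's trial sequence.

    Each block starts with a no-response reference trial. Switch
    transitions among the remaining trials are allocated by exact count
    (``round(p_switch * n_eligible)``) and shuffled, so the switch
    proportion is reproduced at session scale rather than in expectation.
    """
    if cfg.trials_per_block < 2:
        raise InvalidConfigError("trials_per_block must be at least 2")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_eligible = cfg.n_blocks * (cfg.trials_per_block - 1)
    n_switch = int(round(cfg.p_switch * n_eligible))
    flags = np.zeros(n_eligible, dtype=bool)
    flags[:n_switch] = True
    rng.shuffle(flags)

    trials: List[TrialRecord] = []
    k = 0
    for b in range(cfg.n_blocks):
        frame = "reference"
        trials.append(
            TrialRecord(
                block=b,
                position_in_block=0,
                frame=frame,
                switch=False,
                letter="X" if rng.random() < 0.5 else "O",
                requires_response=False,
            )
        )
        for pos in range(1, cfg.trials_per_block):
            sw = bool(flags[k])
            k += 1
            if sw:
                frame = "comparison" if frame == "reference" else "reference"
            trials.append(
                TrialRecord(
                    block=b,
                    position_in_block=pos,
                    frame=frame,
                    switch=sw,
                    letter="X" if rng.random() < 0.5 else "O",
                    requires_response=True,
                )
            )
    return trials


def simulate_behavior(
    trials: List[TrialRecord],
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    subject_rt_shift: float = 0.0,
    subject_cost_shifts: Optional[Dict[str, float]] = None,
) -> List[TrialRecord]:
    """Fill in RT and correctness for response trials.

    RTs are Normal(rt_means[condition] + subject shifts, rt_sd) truncated
    below at 0; draws beyond the response deadline become no-response
    trials (rt and correct stay absent). Correctness is Bernoulli with
    the condition's accuracy probability. ``subject_cost_shifts`` adds a
    per-condition offset (the subject's idiosyncratic gating cost).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    subject_cost_shifts = subject_cost_shifts or {}
    for cond in CONDITIONS:
        if cond not in cfg.rt_means:
            raise InvalidConfigError(f"rt_means missing condition {cond}")
        if cond not in cfg.acc_probs:
            raise InvalidConfigError(f"acc_probs missing condition {cond}")
    out: List[TrialRecord] = []
    for tr in trials:
        tr = TrialRecord(**{**tr.__dict__})
        if tr.requires_response:
            mu = (
                cfg.rt_means[tr.condition]
                + subject_rt_shift
                + subject_cost_shifts.get(tr.condition, 0.0)
            )
            rt = rng.normal(mu, cfg.rt_sd) if cfg.rt_sd > 0 else mu
            while rt <= 0:
                rt = rng.normal(mu, cfg.rt_sd)
            if rt > cfg.rt_deadline:
                tr.rt = None
                tr.correct = None
            else:
                tr.rt = float(rt)
                tr.correct = bool(rng.random() < cfg.acc_probs[tr.condition])
        out.append(tr)
    return out


def trials_to_frame(trials: List[TrialRecord], subject: str = "S00") -> pd.DataFrame:
    """Tabulate a trial list (one row per trial, CSV-ready)."""
    rows = []
    for i, tr in enumerate(trials):
        rows.append(
            {
                "subject": subject,
                "block": tr.block,
                "trial": i,
                "frame": tr.frame,
                "switch": tr.switch,
                "letter": tr.letter,
                "requires_response": tr.requires_response,
                "condition": tr.condition or "",
                "rt_ms": np.nan if tr.rt is None else tr.rt,
                "correct": np.nan if tr.correct is None else bool(tr.correct),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """What was planted: topographies, sampled waveforms, and the time
    windows where any pair of conditions differs."""

    topographies: np.ndarray  # (n_sources, n_channels)
    waveforms: Dict[str, Dict[str, np.ndarray]]  # label -> condition -> samples
    times: np.ndarray
    diff_windows: Dict[Tuple[str, str], List[Tuple[float, float]]]
    source_labels: List[str] = field(default_factory=list)


def _condition_diff_windows(
    waveforms: Dict[str, Dict[str, np.ndarray]], times: np.ndarray, tol: float = 1e-9
) -> Dict[Tuple[str, str], List[Tuple[float, float]]]:
    out: Dict[Tuple[str, str], List[Tuple[float, float]]] = {}
    conds = list(CONDITIONS)
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            differs = np.zeros(len(times), dtype=bool)
            for wf in waveforms.values():
                differs |= np.abs(wf[a] - wf[b]) > tol
            windows = []
            idx = np.flatnonzero(differs)
            if idx.size:
                breaks = np.flatnonzero(np.diff(idx) > 1)
                starts = np.concatenate([[idx[0]], idx[breaks + 1]])
                ends = np.concatenate([idx[breaks], [idx[-1]]])
                windows = [(float(times[s]), float(times[e])) for s, e in zip(starts, ends)]
            out[(a, b)] = windows
    return out


def _spatial_noise_chol(n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Cholesky factor of a smooth random spatial covariance (unit variance
    per channel). Channels sit on a Fibonacci sphere; covariance decays
    with inter-channel distance, making the noise spatially correlated."""
    pos = channel_positions(n_channels)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    length = 0.5 + 0.5 * rng.random()
    cov = np.exp(-(d**2) / (2 * length**2)) + 0.05 * np.eye(n_channels)
    dd = np.sqrt(np.diag(cov))
    cov = cov / np.outer(dd, dd)
    return np.linalg.cholesky(cov)


def channel_positions(n_channels: int) -> np.ndarray:
    """Quasi-uniform electrode positions on the upper unit hemisphere."""
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    z = 1.0 - i / max(n_channels - 1, 1) * 0.95  # stay on the upper cap
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    theta = 2 * np.pi * i / golden
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def gaussian_bump(center_ms: float, width_ms: float, amplitude: float):
    """A transient source waveform: Gaussian bump in time."""

    def wf(t: np.ndarray) -> np.ndarray:
        return amplitude * np.exp(-0.5 * ((t - center_ms) / width_ms) ** 2)

    return wf


def default_sources(
    n_channels: int = 60,
    rng: Optional[np.random.Generator] = None,
    opening_window: Tuple[float, float] = (300.0, 500.0),
    closing_window: Tuple[float, float] = (400.0, 750.0),
    effect_amplitude: float = 8.0,
    base_amplitude: float = 2.0,
    topographies: Optional[np.ndarray] = None,
) -> List[PlantedSource]:
    """Two planted sources with condition-specific transients.

    Source 1 discriminates the reference (gate-opening) conditions inside
    ``opening_window``; source 2 discriminates the comparison
    (gate-closing) conditions inside ``closing_window``. Topographies are
    smooth dipolar-looking patterns with orthogonalized second source, or
    caller-supplied rows.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if topographies is None:
        pos = channel_positions(n_channels)
        topos = []
        for _ in range(2):
            center = rng.normal(size=3)
            center /= np.linalg.norm(center)
            topo = np.exp(-np.linalg.norm(pos - 0.7 * center, axis=1) ** 2 / 0.5)
            topo -= topo.mean()
            topos.append(topo)
        # orthogonalize the second against the first so recovery is clean
        topos[1] -= topos[0] * (topos[1] @ topos[0]) / (topos[0] @ topos[0])
        topographies = np.array([t / np.linalg.norm(t) for t in topos])
    else:
        topographies = np.asarray(topographies, dtype=float)

    def bump_pair(window, strong_cond, weak_conds):
        c = 0.5 * (window[0] + window[1])
        w = (window[1] - window[0]) / 4.0
        wf = {strong_cond: gaussian_bump(c, w, effect_amplitude)}
        for cond in weak_conds:
            wf[cond] = gaussian_bump(c, w, base_amplitude)
        return wf

    opening = PlantedSource(
        topography=topographies[0],
        waveform_by_condition=bump_pair(
            opening_window,
            "switch_reference",
            ["nonswitch_reference", "switch_comparison", "nonswitch_comparison"],
        ),
        trial_jitter_sd=0.0,
        label="opening",
    )
    closing = PlantedSource(
        topography=topographies[1],
        waveform_by_condition=bump_pair(
            closing_window,
            "switch_comparison",
            ["nonswitch_comparison", "switch_reference", "nonswitch_reference"],
        ),
        trial_jitter_sd=0.0,
        label="closing",
    )
    return [opening, closing]


def simulate_epochs(
    trials: List[TrialRecord],
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    subject: str = "S00",
) -> Tuple[EpochSet, GroundTruth]:
    """Forward-model EEG epochs for one session.

    Each trial's epoch is the sum over planted sources of
    topography (x) waveform(condition, t + jitter), plus spatially
    correlated Gaussian noise of standard deviation ``noise_sd``.
    Block-initial no-response trials reuse their frame's nonswitch
    waveform and carry an empty condition label.
    """
    if not cfg.sources:
        raise InvalidConfigError("simulate_epochs requires at least one planted source")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    times = cfg.epoch_times
    n_trials = len(trials)
    n_samples = len(times)
    data = np.zeros((n_trials, cfg.n_channels, n_samples))

    chol = _spatial_noise_chol(cfg.n_channels, rng) if cfg.noise_sd > 0 else None

    waveforms: Dict[str, Dict[str, np.ndarray]] = {}
    for src in cfg.sources:
        if len(src.topography) != cfg.n_channels:
            raise InvalidConfigError(
                f"source {src.label}: topography has {len(src.topography)} entries, "
                f"expected {cfg.n_channels}"
            )
        waveforms[src.label] = {
            cond: src.waveform_by_condition[cond](times) for cond in CONDITIONS
        }

    for i, tr in enumerate(trials):
        cond = tr.condition or f"nonswitch_{tr.frame}"
        for src in cfg.sources:
            if src.trial_jitter_sd > 0:
                shift = rng.normal(0.0, src.trial_jitter_sd)
                wf = src.waveform_by_condition[cond](times - shift)
            else:
                wf = waveforms[src.label][cond]
            data[i] += np.outer(src.topography, wf)
        if cfg.noise_sd > 0:
            white = rng.standard_normal((cfg.n_channels, n_samples))
            data[i] += cfg.noise_sd * (chol @ white)

    condition = np.array([tr.condition or "" for tr in trials], dtype=object)
    epochs = EpochSet(
        data=data, fs=cfg.fs, times=times, condition=condition, subject=subject
    )
    gt = GroundTruth(
        topographies=np.array([s.topography for s in cfg.sources]),
        waveforms=waveforms,
        times=times,
        diff_windows=_condition_diff_windows(waveforms, times),
        source_labels=[s.label for s in cfg.sources],
    )
    return epochs, gt


def simulate_session(
    cfg: SimConfig, subject_index: int = 0
) -> Tuple[List[TrialRecord], EpochSet, GroundTruth]:
    """Trial sequence + behavior + epochs for one subject.

    Per-subject randomness derives deterministically from
    ``(cfg.seed, subject_index)``; the same config reproduces the same
    cohort byte for byte.
    """
    rng = np.random.default_rng([cfg.seed, subject_index])
    subject = f"S{subject_index:02d}"
    trials = simulate_session_behavior(cfg, rng)
    epochs, gt = simulate_epochs(trials, cfg, rng, subject=subject)
    return trials, epochs, gt


def simulate_session_behavior(
    cfg: SimConfig, rng: np.random.Generator
) -> List[TrialRecord]:
    """One subject's trial sequence with behavior filled in, including
    the subject's RT intercept and idiosyncratic gating costs."""
    trials = generate_trial_sequence(cfg, rng)
    shift = rng.normal(0.0, cfg.subject_rt_sd) if cfg.subject_rt_sd > 0 else 0.0
    cost_shifts = {
        "switch_reference": rng.normal(0.0, cfg.opening_cost_sd)
        if cfg.opening_cost_sd > 0
        else 0.0,
        "switch_comparison": rng.normal(0.0, cfg.closing_cost_sd)
        if cfg.closing_cost_sd > 0
        else 0.0,
    }
    return simulate_behavior(
        trials, cfg, rng, subject_rt_shift=shift, subject_cost_shifts=cost_shifts
    )


def simulate_behavior_cohort(cfg: SimConfig) -> pd.DataFrame:
    """Trial/behavior table for a whole cohort (no EEG), one subject per
    ``(cfg.seed, subject_index)`` stream as in :func:`simulate_session`."""
    frames = []
    for s in range(cfg.n_subjects):
        rng = np.random.default_rng([cfg.seed, s])
        trials = simulate_session_behavior(cfg, rng)
        frames.append(trials_to_frame(trials, subject=f"S{s:02d}"))
    return pd.concat(frames, ignore_index=True)
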