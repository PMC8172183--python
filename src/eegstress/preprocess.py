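"""Signal conditioning, windowing and time-window partitioning.

The conditioning chain is the conventional one for scalp EEG band-power
work: a 1 Hz high-pass to remove drift, a 50 Hz low-pass to remove line
noise and high-frequency EMG, downsampling to 250 Hz, and per-channel
baseline (DC) correction against the resting recording.  Each task is then
cut into non-overlapping 1-second windows (one feature row per window), and
each task's window sequence is split into three 200-window slices so the
classifiers can be evaluated on the beginning, middle and end of a task.

The IIR filter is realised as two cascaded 4th-order Butterworth sections
(high-pass then low-pass) applied forward-backward for zero phase — the
standard EEGLAB-equivalent choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .synthetic import Recording

STRESS_TASKS = ("preparation", "speech", "arithmetic")


@dataclass(frozen=True)
class PreprocessConfig:
    hp_cut: float = 1.0
    lp_cut: float = 50.0
    target_fs: float = 250.0
    window_s: float = 1.0
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.hp_cut < self.lp_cut <= self.target_fs / 2):
            raise ValueError("require 0 < hp_cut < lp_cut <= target_fs/2")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")


@dataclass
class WindowedRecording:
    subject_id: str
    group: str
    condition: str
    fs: float
    channels: tuple[str, ...]
    windows: np.ndarray  # n_windows x channels x samples_per_window

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)


#: Window-index ranges (half-open, 0-based) of the three per-task slices.
#: Baseline and preparation (600 windows) split into thirds; speech and
#: arithmetic (300 windows) use [0,200) then [100,300) for both slice 2 and
#: slice 3 — the middle/end slices of a 5-minute task coincide.
_LONG_RANGES = {1: (0, 200), 2: (200, 400), 3: (400, 600)}
_SHORT_RANGES = {1: (0, 200), 2: (100, 300), 3: (100, 300)}


@dataclass(frozen=True)
class TimeWindowPartition:
    """Selects the index-th 200-window slice of each condition's window sequence."""

    index: int
    long_ranges: dict[int, tuple[int, int]] = field(default_factory=lambda: dict(_LONG_RANGES))
    short_ranges: dict[int, tuple[int, int]] = field(default_factory=lambda: dict(_SHORT_RANGES))

    def __post_init__(self) -> None:
        if self.index not in (1, 2, 3):
            raise ValueError("partition index must be 1, 2 or 3")

    def range_for(self, condition: str) -> tuple[int, int]:
        table = self.long_ranges if condition in ("baseline", "preparation") else self.short_ranges
        return table[self.index]


def bandlimit_and_resample(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> Recording:
    """High-pass, low-pass (zero-phase Butterworth), then resample to target_fs.

    Filtering always precedes resampling.  If the input is already at
    target_fs the resampling step is the identity.
    """
    if rec.fs < 2 * cfg.lp_cut:
        raise ValueError(
            f"fs={rec.fs} Hz is below the Nyquist bound 2*lp_cut={2 * cfg.lp_cut} Hz"
        )
    sos_hp = signal.butter(cfg.filter_order, cfg.hp_cut, btype="highpass", fs=rec.fs, output="sos")
    sos_lp = signal.butter(cfg.filter_order, cfg.lp_cut, btype="lowpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos_lp, signal.sosfiltfilt(sos_hp, rec.data, axis=1), axis=1)

    if rec.fs != cfg.target_fs:
        ratio = Fraction(cfg.target_fs / rec.fs).limit_denominator(1000)
        data = signal.resample_poly(data, ratio.numerator, ratio.denominator, axis=1)
    return replace(rec, fs=cfg.target_fs, data=data)


def baseline_correct(task: Recording, baseline: Recording) -> Recording:
    """Subtract the per-channel mean of the baseline recording from the task.

    Passing the baseline as its own task zero-means every baseline channel.
    """
    if task.channels != baseline.channels:
        raise ValueError(f"channel mismatch: {task.channels} vs {baseline.channels}")
    if task.fs != baseline.fs:
        raise ValueError(f"sampling-rate mismatch: {task.fs} vs {baseline.fs}")
    offsets = baseline.data.mean(axis=1, keepdims=True)
    return replace(task, data=task.data - offsets)


def window(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> WindowedRecording:
    """Cut into non-overlapping, contiguous windows; trailing remainder dropped."""
    wlen = int(round(cfg.window_s * rec.fs))
    n_win = rec.n_samples // wlen
    if n_win < 1:
        raise ValueError(f"recording ({rec.n_samples} samples) shorter than one window ({wlen})")
    trimmed = rec.data[:, : n_win * wlen]
    # channels x (n_win * wlen) -> n_win x channels x wlen
    wins = trimmed.reshape(rec.data.shape[0], n_win, wlen).transpose(1, 0, 2)
    return WindowedRecording(
        subject_id=rec.subject_id, group=rec.group, condition=rec.condition,
        fs=rec.fs, channels=rec.channels, windows=wins.copy(),
    )


def select_time_window(wrec: WindowedRecording, part: TimeWindowPartition) -> WindowedRecording:
    """Return the 200-window slice of `wrec` named by the partition."""
    lo, hi = part.range_for(wrec.condition)
    if hi > wrec.n_windows:
        raise ValueError(
            f"partition {part.index} needs windows [{lo},{hi}) but condition "
            f"{wrec.condition!r} has only {wrec.n_windows} windows"
        )
    return replace_windows(wrec, wrec.windows[lo:hi])


def replace_windows(wrec: WindowedRecording, windows: np.ndarray) -> WindowedRecording:
    return WindowedRecording(
        subject_id=wrec.subject_id, group=wrec.group, condition=wrec.condition,
        fs=wrec.fs, channels=wrec.channels, windows=windows,
    )


def reject_high_amplitude_windows(wrec: WindowedRecording, threshold_uv: float) -> WindowedRecording:
    """Optional hook: drop windows whose peak absolute amplitude exceeds a threshold.

    Off by default everywhere; a crude stand-in for artifact rejection on
    recordings that may contain transients.
    """
    peak = np.abs(wrec.windows).max(axis=(1, 2))
    return replace_windows(wrec, wrec.windows[peak <= threshold_uv])


def preprocess_session(
    recordings: list[Recording],
    cfg: PreprocessConfig = PreprocessConfig(),
    baseline_condition: str = "baseline",
) -> list[Recording]:
    """Condition a subject's four recordings: filter/resample all, then
    baseline-correct every task (and the baseline itself) against the
    baseline's per-channel mean."""
    conditioned = {r.condition: bandlimit_and_resample(r, cfg) for r in recordings}
    if baseline_condition not in conditioned:
        raise ValueError(f"no {baseline_condition!r} recording in session")
    base = conditioned[baseline_condition]
    return [baseline_correct(rec, base) for rec in conditioned.values()]
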