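"""Seeded synthetic multi-channel EEG with condition-dependent spectral structure.

Emulates a Trier-Social-Stress-Test-style recording session: a 10-minute
resting baseline, a 10-minute speech-preparation task, a 5-minute public
speech and a 5-minute mental-arithmetic task.  Stress conditions raise
frontal-midline theta and broadband gamma power and depress parietal-midline
alpha power relative to baseline, on top of a 1/f (pink) background — the
spectral signature the band-power, relative-gamma and brain-load-index
biomarkers are designed to pick up.

Each channel is a sum of band-limited Gaussian noise processes (one per
classical EEG band, with a controllable linear gain), pink noise and white
noise.  Band gains are the only thing that differs between conditions, so
expected band powers — and hence the expected values of every downstream
feature — follow analytically from the gain products.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

CONDITIONS = ("baseline", "preparation", "speech", "arithmetic")
CHANNELS = ("Fz", "Cz", "Pz")
BANDS = ("theta", "alpha", "beta", "gamma")

#: Generation band edges in Hz.  Gamma is generated even though only
#: theta/alpha/beta are power features, because relative gamma needs it.
GEN_BAND_EDGES: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (7.0, 13.0),
    "beta": (13.0, 39.0),
    "gamma": (25.0, 45.0),
}

#: Baseline RMS amplitude (µV) of each band-limited component.  Alpha is
#: strongest (posterior dominant rhythm), gamma weakest — the usual resting
#: scalp EEG hierarchy.  Total channel RMS lands in the 5–50 µV range.
BASE_BAND_RMS: dict[str, float] = {
    "theta": 4.0,
    "alpha": 6.0,
    "beta": 3.0,
    "gamma": 1.5,
}

#: Per-condition stress coupling: gains scale by (1 + c * stress_strength).
#: Monotone preparation < arithmetic < speech so that the expected brain-load
#: index and relative gamma order the conditions deterministically.
STRESS_COUPLING: dict[str, float] = {
    "baseline": 0.0,
    "preparation": 0.3,
    "arithmetic": 0.6,
    "speech": 1.0,
}

DEFAULT_DURATIONS: dict[str, float] = {
    "baseline": 600.0,
    "preparation": 600.0,
    "speech": 300.0,
    "arithmetic": 300.0,
}


@dataclass(frozen=True)
class ConditionSpec:
    """Generative recipe for one task condition.

    band_gains maps channel -> band -> linear amplitude multiplier applied
    to that band's baseline RMS.
    """

    name: str
    duration_s: float
    band_gains: dict[str, dict[str, float]]
    noise_sd: float = 1.0
    pink_rms: float = 5.0
    pink_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in CONDITIONS:
            raise ValueError(f"unknown condition {self.name!r}; expected one of {CONDITIONS}")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        for ch, gains in self.band_gains.items():
            for band, g in gains.items():
                if not g > 0:
                    raise ValueError(f"gain for {ch}/{band} must be > 0, got {g}")

    def expected_band_power(self, channel: str, band: str) -> float:
        """Expected power (µV²) of one band-limited component, from the gain product."""
        rms = BASE_BAND_RMS[band] * self.band_gains[channel][band]
        return rms**2


@dataclass
class Recording:
    """A labelled multi-channel EEG segment for one participant x one condition."""

    subject_id: str
    group: str
    condition: str
    fs: float
    channels: tuple[str, ...]
    data: np.ndarray  # channels x samples, µV
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be a channels x samples matrix")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        for required in CHANNELS:
            if required not in self.channels:
                raise ValueError(f"channel {required} missing from {self.channels}")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channels.index(label)]


def _unit_gains() -> dict[str, dict[str, float]]:
    return {ch: {b: 1.0 for b in BANDS} for ch in CHANNELS}


def make_default_protocol(stress_strength: float = 1.0) -> list[ConditionSpec]:
    """Four ConditionSpecs (baseline, preparation, speech, arithmetic).

    Baseline has unit gains.  Stress conditions scale the Fz theta gain and
    the gamma gain on every channel up by (1 + c*stress_strength), and the Pz
    alpha gain down by 1/(1 + c*stress_strength), with condition couplings
    c: preparation 0.3 < arithmetic 0.6 < speech 1.0.
    """
    if not np.isfinite(stress_strength):
        raise ValueError("stress_strength must be finite")
    if stress_strength < 0:
        raise ValueError("stress_strength must be >= 0")

    specs = []
    for name in CONDITIONS:
        gains = _unit_gains()
        factor = 1.0 + STRESS_COUPLING[name] * stress_strength
        gains["Fz"]["theta"] *= factor
        gains["Pz"]["alpha"] /= factor
        for ch in CHANNELS:
            gains[ch]["gamma"] *= factor
        specs.append(ConditionSpec(name=name, duration_s=DEFAULT_DURATIONS[name], band_gains=gains))
    return specs


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to [lo, hi] Hz (zero-phase)."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n)
    return x / np.sqrt(np.mean(x**2))


def synthesize_recording(
    spec: ConditionSpec,
    subject_id: str = "S00",
    group: str = "control",
    fs: float = 250.0,
    seed: int = 0,
) -> Recording:
    """Generate one Recording for `spec`; deterministic given (spec, seed)."""
    if fs < 100.0:
        raise ValueError("fs must be >= 100 Hz: the gamma band (up to 45 Hz) is unrepresentable below")
    n = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(seed)
    data = np.empty((len(CHANNELS), n))
    for i, ch in enumerate(CHANNELS):
        x = np.zeros(n)
        for band in BANDS:
            lo, hi = GEN_BAND_EDGES[band]
            rms = BASE_BAND_RMS[band] * spec.band_gains[ch][band]
            x += rms * _band_limited_noise(rng, n, fs, lo, hi)
        x += spec.pink_rms * _pink_noise(rng, n, spec.pink_exponent)
        x += spec.noise_sd * rng.standard_normal(n)
        data[i] = x
    return Recording(
        subject_id=subject_id, group=group, condition=spec.name,
        fs=fs, channels=CHANNELS, data=data, seed=seed,
    )


def _jitter_spec(spec: ConditionSpec, rng: np.random.Generator, jitter_sd: float) -> ConditionSpec:
    """Multiplicative log-normal gain jitter (keeps every gain positive)."""
    if jitter_sd == 0.0:
        return spec
    gains = {
        ch: {b: g * float(np.exp(rng.normal(0.0, jitter_sd))) for b, g in bands.items()}
        for ch, bands in spec.band_gains.items()
    }
    return replace(spec, band_gains=gains)


def cohort_condition_specs(
    n_nurses: int,
    n_controls: int,
    protocol: list[ConditionSpec] | None = None,
    master_seed: int = 0,
    jitter_sd: float = 0.1,
) -> list[tuple[str, str, ConditionSpec, int]]:
    """Per-(subject, condition) jittered specs and seeds for a cohort.

    Returns (subject_id, group, spec, seed) tuples.  One multiplicative
    log-normal gain draw per subject (shared across that subject's four
    conditions) emulates inter-subject variability; everything descends
    deterministically from master_seed via a SeedSequence spawn tree.
    """
    if n_nurses + n_controls < 1:
        raise ValueError("need at least one subject")
    if n_nurses < 0 or n_controls < 0:
        raise ValueError("group sizes must be non-negative")
    if protocol is None:
        protocol = make_default_protocol()

    ss = np.random.SeedSequence(master_seed)
    out: list[tuple[str, str, ConditionSpec, int]] = []
    groups = ["nurse"] * n_nurses + ["control"] * n_controls
    for subj_idx, group in enumerate(groups):
        subj_ss = ss.spawn(1)[0]
        subject_id = f"{'N' if group == 'nurse' else 'C'}{subj_idx:02d}"
        jitter_rng = np.random.default_rng(subj_ss.spawn(1)[0])
        jitter = {
            ch: {b: float(np.exp(jitter_rng.normal(0.0, jitter_sd))) if jitter_sd else 1.0
                 for b in BANDS}
            for ch in CHANNELS
        }
        for spec in protocol:
            gains = {
                ch: {b: g * jitter[ch][b] for b, g in bands.items()}
                for ch, bands in spec.band_gains.items()
            }
            rec_seed = int(subj_ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            out.append((subject_id, group, replace(spec, band_gains=gains), rec_seed))
    return out


def synthesize_cohort(
    n_nurses: int,
    n_controls: int,
    protocol: list[ConditionSpec] | None = None,
    fs: float = 250.0,
    master_seed: int = 0,
    jitter_sd: float = 0.1,
) -> list[Recording]:
    """All (subject x condition) Recordings for a two-group cohort;
    reproducible from master_seed."""
    return [
        synthesize_recording(spec, subject_id=sid, group=group, fs=fs, seed=seed)
        for sid, group, spec, seed in cohort_condition_specs(
            n_nurses, n_controls, protocol, master_seed, jitter_sd
        )
    ]
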