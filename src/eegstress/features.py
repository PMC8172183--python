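"""Per-window biomarker features: band powers, relative gamma, brain load index.

Three feature sets, one row per 1-second window:

* ``power`` — integrated alpha (7–13 Hz), beta (13–39 Hz) and theta (4–7 Hz)
  band power at the three midline channels Fz, Cz, Pz (9 columns, ordered
  (Fz, Cz, Pz) x (alpha, beta, theta)).
* ``rg`` — relative gamma per channel, RG = AvPower(25–45 Hz) / AvPower(4–13 Hz),
  where AvPower is the mean PSD over the band's frequency bins.  Gamma rises
  relative to the slow rhythms under stress.
* ``bli`` — the brain load index, BLI = Theta(Fz) / Alpha(Pz): cognitive load
  raises frontal-midline theta and suppresses parietal-midline alpha, so the
  ratio increases with load.

All spectra come from Welch's method: 125-sample Hann segments (0.5 s at
250 Hz) with 50% overlap, giving 2 Hz resolution — coarse enough for at
least three averaged periodograms per 1-second window, fine enough to
resolve the 4 Hz lower band edge.  Band intervals are half-open [lo, hi) so
the shared 7 and 13 Hz edges are counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import WindowedRecording


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: require lo < hi, got [{self.lo}, {self.hi})")


THETA = BandDefinition("theta", 4.0, 7.0)
ALPHA = BandDefinition("alpha", 7.0, 13.0)
BETA = BandDefinition("beta", 13.0, 39.0)
GAMMA_NUM = BandDefinition("gamma", 25.0, 45.0)
SLOW_DEN = BandDefinition("slow", 4.0, 13.0)
#: Wider slow-rhythm denominator variant (4–23 Hz) selectable in RG.
SLOW_DEN_WIDE = BandDefinition("slow_wide", 4.0, 23.0)

POWER_BANDS = (ALPHA, BETA, THETA)
POWER_CHANNELS = ("Fz", "Cz", "Pz")


@dataclass(frozen=True)
class WelchConfig:
    nperseg: int = 125
    overlap_frac: float = 0.5
    window: str = "hann"

    @property
    def noverlap(self) -> int:
        return int(self.nperseg * self.overlap_frac)


@dataclass
class WindowedFeatures:
    """Feature matrix with per-row provenance labels.

    matrix is n_windows x d; labels/subject_ids/groups/window_indices are
    parallel per-row arrays.
    """

    feature_set: str
    matrix: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    groups: np.ndarray
    window_indices: np.ndarray
    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        n = self.matrix.shape[0]
        for name in ("labels", "subject_ids", "groups", "window_indices"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows, matrix has {n}")
            setattr(self, name, arr)
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("column_names length must match matrix width")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def subset(self, mask: np.ndarray) -> "WindowedFeatures":
        return WindowedFeatures(
            feature_set=self.feature_set,
            matrix=self.matrix[mask],
            labels=self.labels[mask],
            subject_ids=self.subject_ids[mask],
            groups=self.groups[mask],
            window_indices=self.window_indices[mask],
            column_names=self.column_names,
        )


def concat_features(parts: list[WindowedFeatures]) -> WindowedFeatures:
    if not parts:
        raise ValueError("nothing to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if p.feature_set != first.feature_set or p.column_names != first.column_names:
            raise ValueError("feature sets differ; cannot concatenate")
    return WindowedFeatures(
        feature_set=first.feature_set,
        matrix=np.vstack([p.matrix for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        subject_ids=np.concatenate([p.subject_ids for p in parts]),
        groups=np.concatenate([p.groups for p in parts]),
        window_indices=np.concatenate([p.window_indices for p in parts]),
        column_names=first.column_names,
    )


def _welch_psd(windows: np.ndarray, fs: float, cfg: WelchConfig) -> tuple[np.ndarray, np.ndarray]:
    """PSD of every (window, channel); windows is ... x samples."""
    nseg = min(cfg.nperseg, windows.shape[-1])
    freqs, psd = signal.welch(
        windows, fs=fs, window=cfg.window, nperseg=nseg,
        noverlap=int(nseg * cfg.overlap_frac), axis=-1, detrend=False,
    )
    return freqs, psd


def _band_mask(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    mask = (freqs >= band.lo) & (freqs < band.hi)
    if not mask.any():
        raise ValueError(f"no PSD bins fall in band {band.name} [{band.lo}, {band.hi})")
    return mask


def band_power(
    window: np.ndarray, fs: float, band: BandDefinition, welch: WelchConfig = WelchConfig()
) -> np.ndarray:
    """Integrated band power (µV²) per channel of one channels x samples window."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if band.lo >= fs / 2:
        raise ValueError(f"band {band.name} lies entirely above Nyquist ({fs / 2} Hz)")
    freqs, psd = _welch_psd(window, fs, welch)
    mask = _band_mask(freqs, band)
    df = freqs[1] - freqs[0]
    return psd[..., mask].sum(axis=-1) * df


def _avg_psd(psd: np.ndarray, freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    return psd[..., _band_mask(freqs, band)].mean(axis=-1)


def _row_meta(wrec: WindowedRecording, n: int) -> dict:
    return dict(
        labels=np.full(n, wrec.condition, dtype=object),
        subject_ids=np.full(n, wrec.subject_id, dtype=object),
        groups=np.full(n, wrec.group, dtype=object),
        window_indices=np.arange(n),
    )


def power_features(wrec: WindowedRecording, welch: WelchConfig = WelchConfig()) -> WindowedFeatures:
    """9-column integrated band powers, columns (Fz,Cz,Pz) x (alpha,beta,theta).

    Channels are looked up by label, so input channel order is irrelevant.
    """
    for ch in POWER_CHANNELS:
        if ch not in wrec.channels:
            raise ValueError(f"channel {ch} required for power features")
    ch_idx = [wrec.channel_index(c) for c in POWER_CHANNELS]
    freqs, psd = _welch_psd(wrec.windows, wrec.fs, welch)  # n x channels x bins
    df = freqs[1] - freqs[0]
    cols, names = [], []
    for ci, ch in zip(ch_idx, POWER_CHANNELS):
        for band in POWER_BANDS:
            cols.append(psd[:, ci, _band_mask(freqs, band)].sum(axis=-1) * df)
            names.append(f"{ch}_{band.name}")
    matrix = np.column_stack(cols)
    return WindowedFeatures(
        feature_set="power", matrix=matrix, column_names=tuple(names),
        **_row_meta(wrec, wrec.n_windows),
    )


def relative_gamma(
    wrec: WindowedRecording,
    welch: WelchConfig = WelchConfig(),
    slow_band: BandDefinition = SLOW_DEN,
) -> WindowedFeatures:
    """Per-channel relative gamma: mean PSD over 25–45 Hz / mean PSD over 4–13 Hz.

    Scale-invariant by construction.  Rows whose slow-rhythm denominator is
    zero (flat-zero signal) are rejected with a diagnostic.
    """
    if wrec.fs < 90:
        raise ValueError("fs must be >= 90 Hz to cover the 45 Hz gamma edge")
    ch_idx = [wrec.channel_index(c) for c in POWER_CHANNELS]
    freqs, psd = _welch_psd(wrec.windows, wrec.fs, welch)
    num = _avg_psd(psd[:, ch_idx, :], freqs, GAMMA_NUM)
    den = _avg_psd(psd[:, ch_idx, :], freqs, slow_band)
    bad = (den <= 0).any(axis=1)
    if bad.any():
        raise ValueError(
            f"zero slow-rhythm power in windows {np.flatnonzero(bad).tolist()}; "
            "relative gamma undefined for flat-zero signals"
        )
    matrix = num / den
    return WindowedFeatures(
        feature_set="rg", matrix=matrix,
        column_names=tuple(f"{c}_rg" for c in POWER_CHANNELS),
        **_row_meta(wrec, wrec.n_windows),
    )


def brain_load_index(wrec: WindowedRecording, welch: WelchConfig = WelchConfig()) -> WindowedFeatures:
    """Single-column BLI = integrated theta power at Fz / integrated alpha power at Pz."""
    freqs, psd = _welch_psd(wrec.windows, wrec.fs, welch)
    df = freqs[1] - freqs[0]
    theta_fz = psd[:, wrec.channel_index("Fz"), _band_mask(freqs, THETA)].sum(axis=-1) * df
    alpha_pz = psd[:, wrec.channel_index("Pz"), _band_mask(freqs, ALPHA)].sum(axis=-1) * df
    bad = alpha_pz <= 0
    if bad.any():
        raise ValueError(
            f"zero Pz alpha power in windows {np.flatnonzero(bad).tolist()}; BLI undefined"
        )
    matrix = (theta_fz / alpha_pz)[:, None]
    return WindowedFeatures(
        feature_set="bli", matrix=matrix, column_names=("bli",),
        **_row_meta(wrec, wrec.n_windows),
    )


FEATURE_EXTRACTORS = {
    "power": power_features,
    "rg": relative_gamma,
    "bli": brain_load_index,
}


def write_features_csv(features: WindowedFeatures, path, welch: WelchConfig = WelchConfig()) -> None:
    """Features CSV (provenance columns + feature columns) with a JSON sidecar
    recording the band definitions and Welch settings."""
    import json

    import pandas as pd

    path = str(path)
    df = pd.DataFrame(features.matrix, columns=list(features.column_names))
    df.insert(0, "window_index", features.window_indices)
    df.insert(0, "condition", features.labels)
    df.insert(0, "group", features.groups)
    df.insert(0, "subject_id", features.subject_ids)
    df.to_csv(path, index=False)
    sidecar = {
        "feature_set": features.feature_set,
        "bands": {b.name: [b.lo, b.hi] for b in (THETA, ALPHA, BETA, GAMMA_NUM, SLOW_DEN)},
        "welch": {"nperseg": welch.nperseg, "overlap_frac": welch.overlap_frac,
                  "window": welch.window},
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_features_csv(path, feature_set: str | None = None) -> WindowedFeatures:
    import json
    import os

    import pandas as pd

    df = pd.read_csv(path)
    meta_cols = ["subject_id", "group", "condition", "window_index"]
    feat_cols = [c for c in df.columns if c not in meta_cols]
    if feature_set is None:
        sidecar = str(path) + ".json"
        feature_set = (json.load(open(sidecar))["feature_set"]
                       if os.path.exists(sidecar) else "power")
    return WindowedFeatures(
        feature_set=feature_set,
        matrix=df[feat_cols].to_numpy(float),
        labels=df["condition"].to_numpy(object),
        subject_ids=df["subject_id"].to_numpy(object),
        groups=df["group"].to_numpy(object),
        window_indices=df["window_index"].to_numpy(int),
        column_names=tuple(feat_cols),
    )
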