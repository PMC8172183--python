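"""EDF (European Data Format) export of recordings, plus a cohort manifest.

Writes plain EDF: 256-byte global header, one 256-byte header block per
signal, then 16-bit little-endian data records of one second each.  Subject
and group go in the local-patient-identification field, condition and seed
in the local-recording-identification field; the CSV manifest carries the
same metadata authoritatively.  Reading uses mne.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Recording

_DIGITAL_MAX = 32767
_DIGITAL_MIN = -32768


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write one Recording to an EDF file (one 1-second data record per second)."""
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = len(rec.channels)
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * fs]

    # physical range per channel, symmetric, with headroom
    phys_max = np.maximum(np.abs(data).max(axis=1) * 1.05, 1e-6)
    scaled = np.empty_like(data, dtype=np.int16)
    for i in range(n_sig):
        scaled[i] = np.round(data[i] / phys_max[i] * _DIGITAL_MAX).astype(np.int16)

    header = b"".join([
        _field("0", 8),
        _field(f"{rec.subject_id} {rec.group}", 80),
        _field(f"{rec.condition} seed={rec.seed}", 80),
        _field("01.01.20", 8),
        _field("00.00.00", 8),
        _field(str(256 * (1 + n_sig)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),  # record duration, seconds
        _field(str(n_sig), 4),
    ])
    per_signal = b"".join([
        b"".join(_field(ch, 16) for ch in rec.channels),              # label
        b"".join(_field("AgAgCl electrode", 80) for _ in rec.channels),
        b"".join(_field("uV", 8) for _ in rec.channels),              # physical dim
        b"".join(_field(f"{-phys_max[i]:.6g}"[:8], 8) for i in range(n_sig)),
        b"".join(_field(f"{phys_max[i]:.6g}"[:8], 8) for i in range(n_sig)),
        b"".join(_field(str(_DIGITAL_MIN), 8) for _ in rec.channels),
        b"".join(_field(str(_DIGITAL_MAX), 8) for _ in rec.channels),
        b"".join(_field("", 80) for _ in rec.channels),               # prefiltering
        b"".join(_field(str(fs), 8) for _ in rec.channels),           # samples/record
        b"".join(_field("", 32) for _ in rec.channels),
    ])

    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        for r in range(n_records):
            for i in range(n_sig):
                fh.write(scaled[i, r * fs : (r + 1) * fs].tobytes())


def read_edf(path: str | Path, subject_id: str = "", group: str = "",
             condition: str = "baseline") -> Recording:
    """Read an EDF file back into a Recording (data in µV) via mne."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return Recording(
        subject_id=subject_id, group=group or "control", condition=condition,
        fs=float(raw.info["sfreq"]), channels=tuple(raw.ch_names), data=data,
    )


def write_cohort(recordings: list[Recording], out_dir: str | Path) -> pd.DataFrame:
    """Write one EDF per recording plus a manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}_{rec.condition}.edf"
        write_edf(rec, out_dir / fname)
        rows.append({
            "subject_id": rec.subject_id, "group": rec.group,
            "condition": rec.condition, "path": fname, "seed": rec.seed,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[Recording]:
    """Load every recording listed in a cohort manifest CSV."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    return [
        read_edf(base / row.path, subject_id=str(row.subject_id),
                 group=str(row.group), condition=str(row.condition))
        for row in manifest.itertuples()
    ]
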