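"""End-to-end convenience layer: cohort recordings -> labelled feature tables.

Chains conditioning (filter, resample, baseline correction), 1-second
windowing, the 200-window time-slice selection, and one of the three
biomarker extractors, pooling rows across subjects and conditions.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .features import FEATURE_EXTRACTORS, WindowedFeatures, concat_features
from .preprocess import (
    PreprocessConfig,
    TimeWindowPartition,
    preprocess_session,
    select_time_window,
    window,
)
from .synthetic import Recording


def extract_features(
    recordings: list[Recording],
    feature_set: str = "power",
    cfg: PreprocessConfig = PreprocessConfig(),
    partition: TimeWindowPartition | None = None,
) -> WindowedFeatures:
    """Pooled per-window features for a cohort of (subject x condition) recordings.

    Each subject's four recordings are conditioned together (the task
    recordings are baseline-corrected against that subject's resting
    recording), windowed, sliced to the requested 200-window partition
    (partition 3 — the task's final slice — by default), and featurized.
    """
    if feature_set not in FEATURE_EXTRACTORS:
        raise ValueError(f"feature_set must be one of {tuple(FEATURE_EXTRACTORS)}")
    if partition is None:
        partition = TimeWindowPartition(index=3)
    extractor = FEATURE_EXTRACTORS[feature_set]

    by_subject: dict[str, list[Recording]] = defaultdict(list)
    for rec in recordings:
        by_subject[rec.subject_id].append(rec)

    parts = []
    for subject_id in sorted(by_subject):
        session = preprocess_session(by_subject[subject_id], cfg)
        for rec in session:
            wrec = select_time_window(window(rec, cfg), partition)
            parts.append(extractor(wrec))
    return concat_features(parts)


def raw_amplitude_features(
    recordings: list[Recording],
    cfg: PreprocessConfig = PreprocessConfig(),
    partition: TimeWindowPartition | None = None,
    decimate: int = 5,
) -> WindowedFeatures:
    """Control feature set: the windows' raw amplitudes, flattened.

    Classifying these directly (instead of spectral biomarkers) is the
    negative control; samples may be decimated to keep the dimensionality
    manageable (default every 5th sample: 150 columns at 250 Hz).
    """
    if partition is None:
        partition = TimeWindowPartition(index=3)
    by_subject: dict[str, list[Recording]] = defaultdict(list)
    for rec in recordings:
        by_subject[rec.subject_id].append(rec)

    mats, labels, subjects, groups, widx = [], [], [], [], []
    for subject_id in sorted(by_subject):
        session = preprocess_session(by_subject[subject_id], cfg)
        for rec in session:
            wrec = select_time_window(window(rec, cfg), partition)
            flat = wrec.windows[:, :, ::decimate].reshape(wrec.n_windows, -1)
            mats.append(flat)
            n = wrec.n_windows
            labels.append(np.full(n, rec.condition, dtype=object))
            subjects.append(np.full(n, rec.subject_id, dtype=object))
            groups.append(np.full(n, rec.group, dtype=object))
            widx.append(np.arange(n))
    matrix = np.vstack(mats)
    return WindowedFeatures(
        feature_set="raw_amplitude",
        matrix=matrix,
        labels=np.concatenate(labels),
        subject_ids=np.concatenate(subjects),
        groups=np.concatenate(groups),
        window_indices=np.concatenate(widx),
        column_names=tuple(f"s{i}" for i in range(matrix.shape[1])),
    )
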