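import numpy as np
import pytest

from eegstress import extract_features, make_default_protocol, synthesize_cohort
from eegstress.features import WindowedFeatures


@pytest.fixture(scope="session")
def small_cohort():
    """1 nurse + 1 control, full-length protocol at stress strength 1."""
    return synthesize_cohort(1, 1, make_default_protocol(1.0), fs=250.0, master_seed=7)


@pytest.fixture(scope="session")
def power_feats(small_cohort):
    return extract_features(small_cohort, "power")


@pytest.fixture(scope="session")
def bli_feats(small_cohort):
    return extract_features(small_cohort, "bli")


def make_cluster_features(n_per_class=60, d=5, sep=8.0, seed=0, feature_set="power"):
    """Four well-separated Gaussian clusters labelled by condition."""
    rng = np.random.default_rng(seed)
    conditions = ("baseline", "preparation", "speech", "arithmetic")
    mats, labels = [], []
    for i, cond in enumerate(conditions):
        centre = np.zeros(d)
        centre[i % d] = sep * (1 + i)
        mats.append(centre + rng.standard_normal((n_per_class, d)))
        labels += [cond] * n_per_class
    X = np.vstack(mats)
    n = X.shape[0]
    return WindowedFeatures(
        feature_set=feature_set,
        matrix=X,
        labels=np.array(labels, dtype=object),
        subject_ids=np.array([f"S{i % 4}" for i in range(n)], dtype=object),
        groups=np.array(["nurse" if i % 2 else "control" for i in range(n)], dtype=object),
        window_indices=np.arange(n),
        column_names=tuple(f"f{i}" for i in range(d)),
    )


@pytest.fixture
def cluster_features():
    return make_cluster_features()
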