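"""Feature-space diagnostics: t-SNE embeddings and per-condition summaries.

t-SNE projects a feature set to two dimensions by matching neighbour
distributions (minimising the KL divergence between high- and
low-dimensional joint probabilities); well-separated conditions in the
embedding indicate class structure the classifiers can exploit.  Defaults
follow the protocol used for the biomarker features here: perplexity 10,
5000 iterations, learning rate 1000.  A fractional mode sets the perplexity
to 10% of the row count for users who prefer scaling it with n.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .features import WindowedFeatures


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # n x 2
    feature_set: str
    labels: np.ndarray
    perplexity: float
    n_iter: int
    learning_rate: float
    seed: int
    kl_divergence_final: float


def embed(
    features: WindowedFeatures,
    perplexity: float = 10.0,
    n_iter: int = 5000,
    learning_rate: float = 1000.0,
    seed: int = 0,
    perplexity_frac: float | None = None,
) -> EmbeddingResult:
    """2-D t-SNE embedding of the feature rows; deterministic given seed."""
    n = features.n_rows
    if perplexity_frac is not None:
        perplexity = perplexity_frac * n
    if n <= 3 * perplexity:
        raise ValueError(f"need more than 3*perplexity={3 * perplexity:.0f} rows, got {n}")
    init = "pca" if features.matrix.shape[1] >= 2 else "random"
    tsne = TSNE(
        n_components=2, perplexity=perplexity, max_iter=n_iter,
        learning_rate=learning_rate, random_state=seed, init=init,
    )
    coords = tsne.fit_transform(features.matrix)
    if not np.isfinite(coords).all():
        raise ValueError("t-SNE produced non-finite coordinates")
    return EmbeddingResult(
        coordinates=coords, feature_set=features.feature_set, labels=features.labels,
        perplexity=float(perplexity), n_iter=n_iter, learning_rate=float(learning_rate),
        seed=seed, kl_divergence_final=float(tsne.kl_divergence_),
    )


def feature_summary(features: WindowedFeatures) -> pd.DataFrame:
    """Per-condition mean and standard deviation of every feature column.

    Uses the population standard-deviation convention (divide by n).
    """
    if features.n_rows == 0:
        raise ValueError("empty feature set")
    df = pd.DataFrame(features.matrix, columns=list(features.column_names))
    df["condition"] = features.labels
    grouped = df.groupby("condition", sort=True)
    mean = grouped.mean()
    sd = grouped.std(ddof=0)
    out = pd.concat({"mean": mean, "sd": sd}, axis=1)
    out.columns = [f"{col}_{stat}" for stat, col in out.columns]
    out.insert(0, "feature_set", features.feature_set)
    return out.reset_index()


def plot_embedding(result: EmbeddingResult, path: str | Path) -> None:
    """Scatter of the embedding coloured by condition, saved to `path`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for cond in np.unique(result.labels):
        m = result.labels == cond
        ax.scatter(result.coordinates[m, 0], result.coordinates[m, 1], s=6, label=str(cond))
    ax.legend(markerscale=2, fontsize=8)
    ax.set_title(f"t-SNE of {result.feature_set} (perplexity={result.perplexity:g})")
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def embedding_to_csv(result: EmbeddingResult, path: str | Path) -> None:
    pd.DataFrame({
        "x": result.coordinates[:, 0],
        "y": result.coordinates[:, 1],
        "condition": result.labels,
    }).to_csv(path, index=False)
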