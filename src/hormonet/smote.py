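"""From-scratch SMOTE oversampling.

Synthetic minority instances are linear interpolations between a
minority point x and one of its k nearest same-class neighbours x_R:

    s = x + u * (x_R - x),   u ~ Uniform[0, 1]

New points are drawn until every class reaches the size of the
pre-balancing majority class.  Nearest neighbours are found with
Euclidean distance within the class only; distance ties break on the
lowest row index so results are reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SMOTEConfig", "smote_sample", "balance"]


class SMOTEConfigError(ValueError):
    """Raised when a minority class is too small for the requested k."""


@dataclass(frozen=True)
class SMOTEConfig:
    k_neighbors: int = 5
    seed: int = 0
    #: "train_only" balances a training partition (leakage-safe default);
    #: "full_dataset" balances before splitting, the procedure implied by
    #: balanced train *and* test counts in the benchmark tables.
    scope: str = "train_only"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.scope not in {"train_only", "full_dataset"}:
            raise ValueError(f"unknown scope {self.scope!r}")


def smote_sample(x: np.ndarray, x_nn: np.ndarray, u: float) -> np.ndarray:
    """One interpolated instance s = x + u * (x_nn - x), componentwise."""
    x = np.asarray(x, dtype=float)
    x_nn = np.asarray(x_nn, dtype=float)
    if x.shape != x_nn.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_nn.shape}")
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u must be in [0, 1], got {u}")
    return x + u * (x_nn - x)


def _knn_within_class(cls_rows: np.ndarray, k: int) -> np.ndarray:
    """Indices (n, k) of each row's k nearest same-class neighbours.

    Self is excluded; ties in distance break on lower row index
    (lexicographic sort on (distance, index)).
    """
    n = len(cls_rows)
    d2 = np.sum((cls_rows[:, None, :] - cls_rows[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    # stable argsort gives lowest-index-first among equal distances
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def balance(
    features: np.ndarray,
    labels: np.ndarray,
    config: SMOTEConfig = SMOTEConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample every minority class up to the majority count.

    Returns ``(features_out, labels_out, synthetic_flag)``; original
    rows come first, verbatim and in input order, followed by synthetic
    rows flagged 1.  Already-balanced input is returned unchanged.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or len(features) != len(labels):
        raise ValueError("features must be 2-D with one row per label")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to balance")
    majority = int(counts.max())
    rng = np.random.default_rng(config.seed)

    synth_feats: list[np.ndarray] = []
    synth_labels: list[np.ndarray] = []
    for cls, count in zip(classes, counts):
        deficit = majority - int(count)
        if deficit == 0:
            continue
        if count <= config.k_neighbors:
            raise SMOTEConfigError(
                f"class {cls!r} has {count} rows, <= k_neighbors="
                f"{config.k_neighbors}; use a smaller k"
            )
        cls_idx = np.flatnonzero(labels == cls)
        cls_rows = features[cls_idx]
        nn = _knn_within_class(cls_rows, config.k_neighbors)
        base = rng.integers(0, len(cls_rows), size=deficit)
        pick = rng.integers(0, config.k_neighbors, size=deficit)
        u = rng.random(size=deficit)
        x = cls_rows[base]
        x_r = cls_rows[nn[base, pick]]
        synth_feats.append(x + u[:, None] * (x_r - x))
        synth_labels.append(np.full(deficit, cls, dtype=labels.dtype))

    if not synth_feats:
        return features, labels, np.zeros(len(labels), dtype=int)
    features_out = np.vstack([features, *synth_feats])
    labels_out = np.concatenate([labels, *synth_labels])
    flag = np.concatenate(
        [np.zeros(len(labels), dtype=int), np.ones(len(features_out) - len(labels), dtype=int)]
    )
    return features_out, labels_out, flag
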