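"""Decodability testing of anatomical identity from post-fidget responses.

If cortical areas, layers or Cre-lines differed in their fidget-locked
responses, a classifier should recover those labels from the responses.
The test embeds each neuron's 200-sample mean post-onset z-scored trace
(UMAP by default; PCA and alternative UMAP settings as robustness
variants), balances classes by subsampling to the least prevalent class,
trains a grid-searched gradient-boosted tree classifier on a stratified
85-15 split with 5-fold cross-validation, and reports per-class F1
together with a matched shuffled-label baseline that defines chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.preprocessing import LabelEncoder
from xgboost import XGBClassifier

__all__ = [
    "EMBEDDING_VARIANTS",
    "Embedding",
    "DecodeResult",
    "embed_responses",
    "balance_classes",
    "f1_per_class",
    "train_and_score_decoder",
    "shuffle_baseline",
]

#: the four embedding protocols used for the robustness analysis
EMBEDDING_VARIANTS = {
    "default": dict(method="umap", n_neighbors=20, n_components=2),
    "nn5": dict(method="umap", n_neighbors=5, n_components=2),
    "nn200": dict(method="umap", n_neighbors=200, n_components=2),
    "umap3d": dict(method="umap", n_neighbors=20, n_components=3),
    "pca10": dict(method="pca", n_components=10),
}

DEFAULT_GRID = {
    "max_depth": [2, 4, 6],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [100, 300],
}


@dataclass
class Embedding:
    coords: np.ndarray  # (n_neurons, d)
    method: str
    params: dict


@dataclass
class DecodeResult:
    label_set: str
    classes: list[str]
    f1: dict[str, float]  # per-class F1 on the held-out test set
    mean_f1: float
    seed: int
    best_params: dict = field(default_factory=dict)
    shuffled_mean_f1: float | None = None
    shuffled_sd_f1: float | None = None


def embed_responses(
    post_z: np.ndarray,
    method: str = "umap",
    n_neighbors: int = 20,
    min_dist: float = 0.0,
    n_components: int = 2,
    seed: int = 0,
) -> Embedding:
    """Project post-onset mean responses into a low-dimensional space.

    ``method='umap'`` is the manifold embedding (2- or 3-D); ``'pca'``
    keeps the leading ``n_components`` principal components.  Deterministic
    given the seed.
    """
    x = np.asarray(post_z, dtype=np.float64)
    if method == "pca":
        coords = PCA(n_components=n_components, random_state=seed).fit_transform(x)
        params = {"n_components": n_components}
    elif method == "umap":
        if len(x) < n_neighbors + 1:
            raise ValueError(
                f"UMAP with n_neighbors={n_neighbors} needs more than "
                f"{n_neighbors} points, got {len(x)}"
            )
        import umap  # deferred: numba compilation is slow to import

        reducer = umap.UMAP(
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            n_components=n_components,
            random_state=seed,
        )
        coords = np.asarray(reducer.fit_transform(x), dtype=np.float64)
        params = {
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "n_components": n_components,
        }
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return Embedding(coords=coords, method=method, params={**params, "seed": seed})


def embed_variant(post_z: np.ndarray, variant: str = "default", seed: int = 0) -> Embedding:
    """One of the named robustness variants (see EMBEDDING_VARIANTS)."""
    if variant not in EMBEDDING_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    return embed_responses(post_z, seed=seed, **EMBEDDING_VARIANTS[variant])


def balance_classes(labels, seed: int = 0) -> np.ndarray:
    """Indices subsampling every class (without replacement) down to the
    count of the least prevalent class."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() == 0 or len(classes) == 0:
        raise ValueError("every class must have at least one sample")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = [
        rng.choice(np.flatnonzero(y == c), size=n_min, replace=False) for c in classes
    ]
    return np.sort(np.concatenate(keep))


def f1_per_class(y_true, y_pred) -> dict[str, float]:
    """Per-class F1 = TP / (TP + 0.5 (FP + FN)), one-vs-rest."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    out = {}
    for c in np.unique(y_true):
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        denom = tp + 0.5 * (fp + fn)
        out[str(c)] = tp / denom if denom > 0 else 0.0
    return out


def _make_classifier(seed: int) -> XGBClassifier:
    return XGBClassifier(
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="mlogloss",
        verbosity=0,
    )


def train_and_score_decoder(
    embedding: Embedding | np.ndarray,
    labels,
    label_set: str = "labels",
    test_size: float = 0.15,
    cv_folds: int = 5,
    grid: dict = DEFAULT_GRID,
    seed: int = 0,
    balance: str = "after_split",
) -> DecodeResult:
    """Grid-searched gradient-boosted-tree decoding with per-class F1.

    The data are split 85-15 with stratification; classes are balanced by
    subsampling to the least prevalent class independently within the
    training and test sets (``balance='after_split'``, the default) or
    once before splitting (``'before_split'``).
    """
    x = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    y = np.asarray(labels)
    if len(x) != len(y):
        raise ValueError("embedding and labels length mismatch")
    if not grid:
        raise ValueError("empty hyperparameter grid")

    if balance == "before_split":
        keep = balance_classes(y, seed=seed)
        x, y = x[keep], y[keep]

    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=test_size, stratify=y, random_state=seed
    )
    if balance == "after_split":
        idx_train = idx_train[balance_classes(y[idx_train], seed=seed)]
        idx_test = idx_test[balance_classes(y[idx_test], seed=seed + 1)]
    elif balance != "before_split":
        raise ValueError(f"unknown balance mode {balance!r}")

    enc = LabelEncoder().fit(y)
    search = GridSearchCV(
        _make_classifier(seed),
        grid,
        cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    search.fit(x[idx_train], enc.transform(y[idx_train]))
    pred = enc.inverse_transform(search.predict(x[idx_test]))
    f1 = f1_per_class(y[idx_test], pred)
    return DecodeResult(
        label_set=label_set,
        classes=sorted(map(str, enc.classes_)),
        f1=f1,
        mean_f1=float(np.mean(list(f1.values()))),
        seed=seed,
        best_params=dict(search.best_params_),
    )


def shuffle_baseline(
    embedding: Embedding | np.ndarray,
    labels,
    n_shuffles: int = 20,
    seed: int = 0,
    **decoder_kwargs,
) -> tuple[float, float, list[float]]:
    """Chance-level F1 from decoders trained on permuted labels.

    Labels are permuted (marginal counts preserved) and the identical
    training protocol is re-run ``n_shuffles`` times; returns
    (mean, SD, per-shuffle mean-F1 list).
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    scores = []
    for i in range(n_shuffles):
        perm = rng.permutation(len(y))
        res = train_and_score_decoder(
            embedding, y[perm], seed=seed + i, **decoder_kwargs
        )
        scores.append(res.mean_f1)
    return float(np.mean(scores)), float(np.std(scores)), scores


def decode_with_baseline(
    embedding: Embedding | np.ndarray,
    labels,
    label_set: str = "labels",
    n_shuffles: int = 20,
    seed: int = 0,
    **decoder_kwargs,
) -> DecodeResult:
    """Observed decoding plus its matched shuffled-label baseline."""
    res = train_and_score_decoder(
        embedding, labels, label_set=label_set, seed=seed, **decoder_kwargs
    )
    mu, sd, _ = shuffle_baseline(
        embedding, labels, n_shuffles=n_shuffles, seed=seed + 500, **decoder_kwargs
    )
    res.shuffled_mean_f1, res.shuffled_sd_f1 = mu, sd
    return res
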