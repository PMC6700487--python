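"""Dataset characterization: normalization, 2-D embedding, histograms,
and random-forest feature ranking.

These are the standard sanity views of a positive/unlabeled hairpin
dataset: z-score the 77 features, project positives plus a random
unlabeled subsample with t-SNE, summarize per-feature class histograms,
and rank features by random-forest impurity importance averaged across
datasets (rank 0 = most important).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE

from .errors import InputError
from .features import FEATURE_NAMES
from .hairpin_extraction import LABEL_POSITIVE, LABEL_UNLABELED

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Rows of 77 canonical features plus a class label per row."""

    ids: list[str]
    X: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self):
        if list(self.X.columns) != list(FEATURE_NAMES):
            raise InputError("feature matrix columns must be the canonical 77 names")
        if self.X.isna().any().any():
            raise InputError("feature matrix contains missing values")
        if not (len(self.ids) == len(self.X) == len(self.labels)):
            raise InputError("ids, rows and labels must align")
        self.labels = np.asarray(self.labels, dtype=object)

    @classmethod
    def from_feature_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        """Build from a feature CSV frame (see features.read_feature_csv)."""
        return cls(
            ids=df["id"].tolist(),
            X=df[list(FEATURE_NAMES)].astype(float).copy(),
            labels=df["label"].to_numpy(),
        )

    @property
    def n_rows(self) -> int:
        return len(self.X)


def normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Z-score each column (subtract mean, divide by standard deviation).

    Zero-variance columns become all zeros with a warning.  Idempotent up
    to floating error.
    """
    if matrix.n_rows < 2:
        raise InputError("normalization needs at least 2 rows")
    X = matrix.X.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    flat = sd == 0.0
    if flat.any():
        logger.warning(
            "%d constant feature column(s) set to zero: %s",
            int(flat.sum()),
            [FEATURE_NAMES[i] for i in np.where(flat)[0][:5]],
        )
    sd_safe = np.where(flat, 1.0, sd)
    Z = (X - mean) / sd_safe
    Z[:, flat] = 0.0
    return FeatureMatrix(
        ids=list(matrix.ids),
        X=pd.DataFrame(Z, columns=list(FEATURE_NAMES)),
        labels=matrix.labels.copy(),
    )


def embed_2d(
    matrix: FeatureMatrix, n_unlabeled: int, seed: int
) -> pd.DataFrame:
    """t-SNE projection of all positives plus a seeded unlabeled subsample.

    Returns a frame with columns id, x, y, label.  Perplexity is
    min(30, (rows - 1) / 3) so small matrices remain embeddable.
    """
    if matrix.n_rows < 5:
        raise InputError("embedding needs at least 5 rows")
    labels = matrix.labels
    pos_idx = np.where(labels == LABEL_POSITIVE)[0]
    unl_idx = np.where(labels != LABEL_POSITIVE)[0]
    if n_unlabeled > len(unl_idx):
        raise InputError(
            f"requested {n_unlabeled} unlabeled rows but only {len(unl_idx)} available"
        )
    rng = np.random.default_rng(seed)
    take = rng.choice(unl_idx, size=n_unlabeled, replace=False) if n_unlabeled else []
    keep = np.sort(np.concatenate([pos_idx, np.asarray(take, dtype=int)]))
    X = matrix.X.to_numpy(dtype=float)[keep]
    perplexity = min(30.0, (len(keep) - 1) / 3.0)
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    ).fit_transform(X)
    return pd.DataFrame(
        {
            "id": [matrix.ids[i] for i in keep],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "label": labels[keep],
        }
    )


def histogram_summary(
    matrix: FeatureMatrix, features: Sequence[str], bins: int = 20
) -> pd.DataFrame:
    """Per-feature, per-class binned counts with shared bin edges.

    Tidy frame: feature, label, bin_left, bin_right, count.
    """
    unknown = [f for f in features if f not in FEATURE_NAMES]
    if unknown:
        raise InputError(
            f"unknown feature name(s) {unknown}; valid names are the canonical 77 "
            f"(e.g. {FEATURE_NAMES[:3]} ... {FEATURE_NAMES[-3:]})"
        )
    rows = []
    for feat in features:
        col = matrix.X[feat].to_numpy(dtype=float)
        edges = np.histogram_bin_edges(col, bins=bins)
        for label in (LABEL_POSITIVE, LABEL_UNLABELED):
            counts, _ = np.histogram(col[matrix.labels == label], bins=edges)
            for k in range(bins):
                rows.append(
                    {
                        "feature": feat,
                        "label": label,
                        "bin_left": edges[k],
                        "bin_right": edges[k + 1],
                        "count": int(counts[k]),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class FeatureRanking:
    """Per-dataset ranks (0 = most important) and their average."""

    per_dataset: pd.DataFrame  # features x datasets
    average: pd.Series

    def top(self, k: int = 5) -> pd.Series:
        return self.average.sort_values().head(k)


def rank_features(
    datasets: Sequence[FeatureMatrix], n_trees: int = 10, seed: int = 0
) -> FeatureRanking:
    """Rank features by impurity importance, averaged across datasets.

    Per dataset a random forest separates positive from unlabeled rows;
    features are ranked by decreasing importance with ties broken by
    canonical feature order, so each dataset's ranks are a permutation
    of 0..76.
    """
    if not datasets:
        raise InputError("rank_features needs at least one dataset")
    cols = {}
    for d_idx, matrix in enumerate(datasets):
        y = (matrix.labels == LABEL_POSITIVE).astype(int)
        if len(np.unique(y)) < 2:
            raise InputError(
                f"dataset {d_idx} has a single class; ranking needs both "
                "positive and unlabeled rows"
            )
        forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        forest.fit(matrix.X.to_numpy(dtype=float), y)
        importances = forest.feature_importances_
        order = np.lexsort((np.arange(77), -importances))
        ranks = np.empty(77, dtype=int)
        ranks[order] = np.arange(77)
        cols[f"dataset_{d_idx}"] = ranks
    per_dataset = pd.DataFrame(cols, index=list(FEATURE_NAMES))
    average = per_dataset.mean(axis=1)
    average.name = "average_rank"
    return FeatureRanking(per_dataset=per_dataset, average=average)


def write_ranking_csv(ranking: FeatureRanking, path) -> None:
    out = ranking.per_dataset.copy()
    out["average_rank"] = ranking.average
    out.index.name = "feature"
    out.to_csv(path)
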