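"""Per-residue random-forest classifiers with Gini feature importance.

One forest is trained per residue type (S, T or Y). Trees are grown on
bootstrap samples with Gini-impurity splits; the default forest size is
100 trees, past which accuracy plateaus on this problem. A feature's
importance is its impurity reduction summed over the nodes that split on
it and averaged across trees (scikit-learn's mean decrease in impurity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureSchema

DEFAULT_N_TREES = 100
DEFAULT_THRESHOLD = 0.5


@dataclass
class ModelBundle:
    """A trained forest plus the schema and parameters it was trained under."""

    residue: str
    forest: RandomForestClassifier
    schema: FeatureSchema
    params: dict
    metadata: dict = field(default_factory=dict)

    @property
    def selected_feature_indices(self) -> list[int] | None:
        """1-based global schema indices the forest was trained on, if a subset."""
        return self.params.get("selected_feature_indices")

    def _columns(self) -> np.ndarray:
        sel = self.selected_feature_indices
        if sel is None:
            return np.arange(self.schema.total_length)
        return np.asarray(sel, dtype=int) - 1


def _validate_matrix(X: np.ndarray, schema: FeatureSchema) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != schema.total_length:
        raise ValueError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"schema expects {schema.total_length}"
        )
    return X


def train(
    X: np.ndarray,
    y: Sequence[int],
    residue: str,
    schema: FeatureSchema,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    feature_subset: Sequence[int] | None = None,
    metadata: dict | None = None,
) -> ModelBundle:
    """Fit a Gini-split bootstrap forest; reproducible for a fixed seed.

    ``feature_subset`` holds 1-based global schema indices; when given,
    only those columns are used (the bundle remembers them and slices
    full-width matrices at prediction time).
    """
    X = _validate_matrix(X, schema)
    y = np.asarray(y, dtype=int)
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 examples of each class")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    subset = None
    if feature_subset is not None:
        subset = sorted(int(i) for i in feature_subset)
        if len(set(subset)) != len(subset):
            raise ValueError("feature_subset contains duplicates")
        if subset and (subset[0] < 1 or subset[-1] > schema.total_length):
            raise ValueError("feature_subset indices out of schema range")
        X = X[:, np.asarray(subset) - 1]
    forest = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    params = {
        "n_trees": n_trees,
        "criterion": "gini",
        "seed": seed,
        "selected_feature_indices": subset,
        "max_depth": forest.max_depth,
        "max_features": forest.max_features,
    }
    meta = dict(metadata or {})
    meta.setdefault("n_positive", int((y == 1).sum()))
    meta.setdefault("n_negative", int((y == 0).sum()))
    return ModelBundle(residue=residue, forest=forest, schema=schema, params=params, metadata=meta)


def predict(
    bundle: ModelBundle, X: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Positive-class probability (mean of tree votes) and the class call.

    The call is positive iff probability >= threshold (ties go positive).
    ``X`` must carry the bundle's full schema width; a trained subset is
    sliced internally.
    """
    X = _validate_matrix(X, bundle.schema)
    pos_col = list(bundle.forest.classes_).index(1)
    proba = bundle.forest.predict_proba(X[:, bundle._columns()])[:, pos_col]
    return proba, proba >= threshold


def feature_importance(bundle: ModelBundle) -> pd.DataFrame:
    """Gini importance table: (feature_index, name, importance), sorted
    descending with ties broken by lower index."""
    cols = bundle._columns()
    table = pd.DataFrame(
        {
            "feature_index": cols + 1,
            "name": [bundle.schema.names[c] for c in cols],
            "importance": bundle.forest.feature_importances_,
        }
    )
    table = table.sort_values(
        ["importance", "feature_index"], ascending=[False, True], kind="stable"
    )
    return table.reset_index(drop=True)


def select_top_k(importance: pd.DataFrame, k: int) -> list[int]:
    """1-based indices of the k highest-importance features."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(importance):
        raise ValueError(f"k={k} exceeds table length {len(importance)}")
    return [int(i) for i in importance["feature_index"].iloc[:k]]


def train_with_selection(
    X: np.ndarray,
    y: Sequence[int],
    residue: str,
    schema: FeatureSchema,
    top_k: int,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    metadata: dict | None = None,
) -> ModelBundle:
    """Two-pass training: full fit, rank by Gini importance, refit on top k."""
    full = train(X, y, residue, schema, n_trees=n_trees, seed=seed, metadata=metadata)
    top = select_top_k(feature_importance(full), top_k)
    return train(
        X, y, residue, schema, n_trees=n_trees, seed=seed,
        feature_subset=top, metadata=metadata,
    )
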