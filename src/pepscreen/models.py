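"""Random Forest surrogate models for rule-violation counts.

The estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and wrap
``RandomForestClassifier`` / ``RandomForestRegressor`` with library-default
hyperparameters unless explicitly overridden. A classifier predicts the
violation count as a class label; a regressor predicts a continuous value
which :meth:`ViolationCountRegressor.predict_counts` rounds half-away-from-
zero and clips to ``[0, max_violations(rule)]``.

``train_model`` / ``predict_counts`` / ``save_model`` / ``load_model`` are
the pipeline-level wrappers: they attach rule metadata (thresholds
fingerprint, dataset provenance) to the fitted estimator and persist it as a
joblib artifact plus a human-readable JSON sidecar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .data import LabelledDataset
from .errors import ConfigurationError, FeatureLayoutError, IntegrityError
from .rules import builtin_ruleset

PARITY_TREE_COUNTS = (10, 20, 30)


@dataclass(frozen=True)
class ModelSpec:
    """What to train: task, rule, ensemble size, representation, seed."""

    task: str  # "classifier" | "regressor"
    rule: str
    n_trees: int
    representation: str = "descriptors"
    seed: int = 0
    variant: str | None = None  # rule variant (muegge core6/full)
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.task not in ("classifier", "regressor"):
            raise ConfigurationError(f"unknown task {self.task!r}")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")

    @property
    def parity(self) -> bool:
        """Whether the ensemble size matches one of the reference configurations."""
        return self.n_trees in PARITY_TREE_COUNTS


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


class _ForestBase(BaseEstimator):
    """Shared plumbing: feature-layout bookkeeping and validation."""

    def _store_layout(self, X):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]

    def _check_layout(self, X):
        check_is_fitted(self, "forest_")
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            expected = list(self.feature_names_in_)
            got = list(X.columns)
            if got != expected:
                missing = [c for c in expected if c not in got]
                extra = [c for c in got if c not in expected]
                raise FeatureLayoutError(
                    f"feature layout mismatch: missing {missing}, unexpected {extra}"
                )
            return X[expected].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise FeatureLayoutError(
                f"expected {self.n_features_in_} features, got {X.shape[1] if X.ndim == 2 else 'non-2D input'}"
            )
        return X

    def _max_count(self) -> int:
        return builtin_ruleset(self.rule, variant=self.variant).max_violations


class ViolationCountClassifier(ClassifierMixin, _ForestBase):
    """Random Forest classifier over integer violation-count classes."""

    def __init__(self, rule: str = "ro5", n_trees: int = 10, seed: int = 0,
                 variant: str | None = None, hyperparameters: dict | None = None):
        self.rule = rule
        self.n_trees = n_trees
        self.seed = seed
        self.variant = variant
        self.hyperparameters = hyperparameters

    def fit(self, X, y):
        y = np.asarray(y)
        if len(y) != len(X):
            raise ConfigurationError("feature/target length mismatch")
        if len(np.unique(y)) == 1:
            warnings.warn(
                f"single-class target for rule {self.rule!r}; classifier will "
                "predict that class everywhere"
            )
        self._store_layout(X)
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            random_state=self.seed,
            **(self.hyperparameters or {}),
        ).fit(Xv, y)
        self.classes_ = self.forest_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        Xv = self._check_layout(X)
        return self.forest_.predict(Xv).astype(np.int64)

    def predict_counts(self, X) -> np.ndarray:
        return self.predict(X)

    def predict_proba(self, X) -> np.ndarray:
        """Per-class tree-vote fractions; the score source for ROC curves."""
        Xv = self._check_layout(X)
        return self.forest_.predict_proba(Xv)


class ViolationCountRegressor(RegressorMixin, _ForestBase):
    """Random Forest regressor whose outputs are mapped back to integer counts."""

    def __init__(self, rule: str = "ro5", n_trees: int = 10, seed: int = 0,
                 variant: str | None = None, hyperparameters: dict | None = None):
        self.rule = rule
        self.n_trees = n_trees
        self.seed = seed
        self.variant = variant
        self.hyperparameters = hyperparameters

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ConfigurationError("feature/target length mismatch")
        self._store_layout(X)
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            random_state=self.seed,
            **(self.hyperparameters or {}),
        ).fit(Xv, y)
        return self

    def predict(self, X) -> np.ndarray:
        """Raw ensemble mean (continuous)."""
        Xv = self._check_layout(X)
        return self.forest_.predict(Xv)

    def predict_counts(self, X) -> np.ndarray:
        """Integer counts: round half-away-from-zero, clip to the rule's range."""
        raw = self.predict(X)
        return np.clip(_round_half_away(raw), 0, self._max_count())


@dataclass
class TrainedModel:
    """A fitted estimator plus the metadata needed to apply it safely."""

    spec: ModelSpec
    estimator: ViolationCountClassifier | ViolationCountRegressor
    feature_names: list[str]
    thresholds_fingerprint: str
    provenance: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return self.spec.n_trees


def _make_estimator(spec: ModelSpec):
    cls = ViolationCountClassifier if spec.task == "classifier" else ViolationCountRegressor
    return cls(
        rule=spec.rule,
        n_trees=spec.n_trees,
        seed=spec.seed,
        variant=spec.variant,
        hyperparameters=dict(spec.hyperparameters) or None,
    )


def train_model(train: LabelledDataset, spec: ModelSpec) -> TrainedModel:
    """Fit a Random Forest surrogate on one rule's violation counts."""
    if train.n == 0:
        raise ConfigurationError("training dataset is empty")
    if spec.rule not in train.targets:
        raise ConfigurationError(
            f"rule {spec.rule!r} absent from dataset targets {sorted(train.targets)}"
        )
    est = _make_estimator(spec)
    X = pd.DataFrame(train.features, columns=train.feature_names)
    est.fit(X, train.targets[spec.rule])
    rs_meta = train.provenance.get("rulesets", {}).get(spec.rule)
    fingerprint = (
        rs_meta["fingerprint"]
        if rs_meta
        else builtin_ruleset(spec.rule, variant=spec.variant).thresholds_fingerprint()
    )
    provenance = {
        "n_train_rows": train.n,
        "representation": train.representation,
        "split": train.provenance.get("split"),
    }
    return TrainedModel(
        spec=spec,
        estimator=est,
        feature_names=list(train.feature_names),
        thresholds_fingerprint=fingerprint,
        provenance=provenance,
    )


def predict_counts(model: TrainedModel, features) -> np.ndarray:
    """Integer violation counts for a feature matrix or DataFrame.

    The feature layout must match the training layout; mismatches raise
    :class:`FeatureLayoutError` listing the offending columns.
    """
    if isinstance(features, pd.DataFrame):
        return model.estimator.predict_counts(features)
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != len(model.feature_names):
        raise FeatureLayoutError(
            f"expected {len(model.feature_names)} features "
            f"({model.feature_names[:5]}...), got shape {features.shape}"
        )
    return model.estimator.predict_counts(features)


def prediction_table(models: Sequence[TrainedModel], features, ids) -> pd.DataFrame:
    """Long-form prediction CSV rows: ``id, rule, task, n_trees, predicted_violations``."""
    frames = []
    for m in models:
        frames.append(
            pd.DataFrame(
                {
                    "id": ids,
                    "rule": m.spec.rule,
                    "task": m.spec.task,
                    "n_trees": m.spec.n_trees,
                    "predicted_violations": predict_counts(m, features),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist ``<path>`` (joblib ensemble) + ``<path>.meta.json`` sidecar."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    meta = {
        "spec": asdict(model.spec),
        "feature_names": model.feature_names,
        "thresholds_fingerprint": model.thresholds_fingerprint,
        "provenance": model.provenance,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def load_model(path: str | Path) -> TrainedModel:
    """Load a model artifact, verifying the sidecar against the ensemble."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if not sidecar.exists():
        raise IntegrityError(f"missing metadata sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
        spec = ModelSpec(**meta["spec"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise IntegrityError(f"corrupted metadata sidecar {sidecar}: {exc}") from exc
    estimator = joblib.load(path)
    if estimator.n_trees != spec.n_trees or estimator.rule != spec.rule:
        raise IntegrityError(
            "metadata/ensemble mismatch: sidecar says "
            f"{spec.rule}/{spec.n_trees} trees, artifact has "
            f"{estimator.rule}/{estimator.n_trees}"
        )
    expected_task = "classifier" if isinstance(estimator, ViolationCountClassifier) else "regressor"
    if spec.task != expected_task:
        raise IntegrityError(f"metadata/ensemble mismatch: task {spec.task!r} vs {expected_task!r}")
    return TrainedModel(
        spec=spec,
        estimator=estimator,
        feature_names=list(meta["feature_names"]),
        thresholds_fingerprint=meta["thresholds_fingerprint"],
        provenance=meta.get("provenance", {}),
    )
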