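"""Individual feature-based predictors.

One classifier is trained per feature encoder; ensembles consume only the
calibrated positive-class probability each predictor emits, so the engine
(random forest, RBF-kernel SVM, or MLP) is swappable without touching the
ensemble layer.

Defaults follow the benchmark configuration: random forest with 200 trees and
library defaults elsewhere.  SVM probabilities come from Platt-style
calibration (the margin itself is not a probability); random-forest
probability is the fraction of trees voting positive.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, StateError, TrainingError
from .feature_encoders import FeatureSpec, DEFAULT_SPECS, encode_matrix
from .sequence_io import DnaSequence, LabeledDataset

ENGINE_KINDS = ("random_forest", "svm_rbf", "mlp")


@dataclass(frozen=True)
class ClassifierEngine:
    """Classifier family + hyperparameters + seed.

    ``hyperparameters`` are passed through to the scikit-learn estimator;
    anything not given stays at the library default.
    """

    kind: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ENGINE_KINDS:
            raise ConfigError(
                f"unknown engine kind {self.kind!r}; expected one of {ENGINE_KINDS}"
            )
        if self.kind == "random_forest":
            n = self.hyperparameters.get("n_estimators", 200)
            if n < 1:
                raise ConfigError(f"random forest needs >= 1 tree, got {n}")

    def build(self):
        """Fresh unfitted estimator (a Pipeline for scale-sensitive engines)."""
        params = dict(self.hyperparameters)
        if self.kind == "random_forest":
            params.setdefault("n_estimators", 200)
            return RandomForestClassifier(random_state=self.seed, **params)
        if self.kind == "svm_rbf":
            params.setdefault("kernel", "rbf")
            # Platt-style sigmoid calibration: the SVM margin is not a probability
            clf = CalibratedClassifierCV(
                SVC(random_state=self.seed, **params), ensemble=False
            )
        else:
            clf = MLPClassifier(random_state=self.seed, **params)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class BasePredictor:
    """A fitted (spec, engine) pair exposing positive-class probabilities."""

    spec: FeatureSpec
    engine: ClassifierEngine
    model: object | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def fitted(self) -> bool:
        return self.model is not None

    def fit_matrix(self, X: np.ndarray, y: np.ndarray) -> "BasePredictor":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise TrainingError(
                f"base predictor {self.spec.cache_key()}: training data has a "
                "single class"
            )
        model = self.engine.build()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
        self.model = model
        self.manifest = {
            "feature": self.spec.index or self.spec.cache_key(),
            "engine": self.engine.kind,
            "seed": self.engine.seed,
            "n_train": int(X.shape[0]),
            "data_hash": hashlib.sha256(
                np.ascontiguousarray(X).tobytes() + y.tobytes()
            ).hexdigest()[:16],
        }
        return self

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise StateError("predictor is not fitted")
        pos_col = list(self.model.classes_).index(1)
        return self.model.predict_proba(X)[:, pos_col]

    def predict_proba(self, seqs: Sequence[DnaSequence]) -> np.ndarray:
        """One probability in [0, 1] per sequence, order preserved."""
        return self.predict_proba_matrix(encode_matrix(seqs, self.spec))

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "BasePredictor":
        return joblib.load(path)


def train_base_predictor(
    data: LabeledDataset,
    spec: FeatureSpec | str,
    engine: ClassifierEngine | None = None,
    X: np.ndarray | None = None,
) -> BasePredictor:
    """Fit one individual feature-based predictor.

    ``X`` may supply a precomputed encoding of ``data.sequences`` for the
    given spec (the encoders are deterministic per sequence, so caching
    across folds is leakage-free).
    """
    if isinstance(spec, str):
        spec = DEFAULT_SPECS[spec]
    engine = engine or ClassifierEngine()
    if X is None:
        X = encode_matrix(data.sequences, spec)
    return BasePredictor(spec, engine).fit_matrix(X, data.label_array())


def predict_proba(predictor: BasePredictor, seqs: Sequence[DnaSequence]) -> np.ndarray:
    """Functional alias for :meth:`BasePredictor.predict_proba`."""
    return predictor.predict_proba(seqs)


def train_all(
    data: LabeledDataset,
    specs: Sequence[FeatureSpec | str] | None = None,
    engine: ClassifierEngine | None = None,
    feature_cache: dict | None = None,
) -> list[BasePredictor]:
    """Train one predictor per spec (defaults: all seventeen F1..F17).

    ``feature_cache`` maps spec cache keys to full-dataset matrices; used by
    the cross-validation harness to avoid re-encoding per fold.
    """
    if specs is None:
        specs = list(DEFAULT_SPECS.values())
    if len(specs) == 0:
        raise ConfigError("train_all: empty spec list")
    resolved = [DEFAULT_SPECS[s] if isinstance(s, str) else s for s in specs]
    predictors = []
    errors = []
    for spec in resolved:
        X = feature_cache.get(spec.cache_key()) if feature_cache else None
        try:
            predictors.append(train_base_predictor(data, spec, engine, X=X))
        except Exception as exc:  # aggregate with spec labels
            errors.append(f"{spec.index or spec.cache_key()}: {exc}")
    if errors:
        raise TrainingError("training failed for: " + "; ".join(errors))
    return predictors
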