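"""Classifier training, model persistence, and per-molecule SOM ranking.

A model is a scikit-learn pipeline — feature-selection stages followed by an
SVM, random-forest, or gradient-boosting classifier — whose hyperparameters
are chosen by grid search under stratified 10-fold cross-validation. The
selection stages are refitted inside every training fold (never on held-out
rows), the best grid point is refitted on all rows, and all per-fold scores
are retained for audit.

At predict time a molecule's candidate sites are enumerated, featurized with
the model's fingerprint recipe, and scored; the ranking is sorted by score
descending with ties broken by ascending atom index. Tree ensembles score
with their positive-class probability; SVMs score with a logistic squash of
the raw decision value — a monotone map to (0, 1), so the ranking equals the
raw-score ranking while avoiding the nondeterminism of internal probability
calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
import sklearn
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import VarianceThreshold
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from . import __version__ as _pkg_version
from .chem import StandardMolecule
from .errors import ConfigError, ModelArchiveError, NumericError, StratificationError
from .features import AtomFingerprintSpec, TopPercentileSelector, _SignFixedPCA, featurize_site
from .sites import SiteTypeDefinition, enumerate_candidate_sites

__all__ = [
    "ALGORITHMS",
    "DEFAULT_GRIDS",
    "ModelConfig",
    "TrainedSomModel",
    "RankedPrediction",
    "cross_validated_grid_search",
    "rank_sites",
    "persist_model",
    "load_model",
]

ALGORITHMS = ("SVM", "RF", "GBDT")

# Reconstructed search grids (the original supplementary grids are not
# reproduced here); override per run via ModelConfig.hyperparameter_grid.
DEFAULT_GRIDS = {
    "SVM": {
        "clf__kernel": ["rbf", "linear"],
        "clf__C": [0.1, 1.0, 10.0, 100.0],
        "clf__gamma": ["scale", 0.01, 0.001],
    },
    "RF": {
        "clf__n_estimators": [100, 300, 500],
        "clf__max_depth": [None, 5, 10],
    },
    "GBDT": {
        "clf__learning_rate": [0.05, 0.1, 0.2],
        "clf__n_estimators": [100, 300],
        "clf__max_depth": [2, 3, 5],
    },
}

_METRIC_ALIASES = {"AUC": "roc_auc", "roc_auc": "roc_auc", "F1": "f1", "f1": "f1"}


@dataclass
class ModelConfig:
    """Everything needed to reproduce a training run."""

    algorithm: str = "SVM"
    fingerprint_spec: AtomFingerprintSpec = field(
        default_factory=lambda: AtomFingerprintSpec("AtomPair", 2048)
    )
    hyperparameter_grid: Optional[dict] = None  # None -> DEFAULT_GRIDS[algorithm]
    selector_recipe: list[dict] = field(default_factory=lambda: [{"method": "VT", "threshold": 0.0}])
    cv_folds: int = 10
    cv_seed: int = 7
    selection_metric: str = "AUC"
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.cv_folds < 2:
            raise ConfigError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.selection_metric not in _METRIC_ALIASES:
            raise ConfigError(
                f"selection_metric must be one of {sorted(set(_METRIC_ALIASES))}"
            )
        grid = self.hyperparameter_grid
        if grid is not None:
            for name, values in grid.items():
                if not isinstance(values, (list, tuple)) or len(values) == 0:
                    raise ConfigError(f"grid entry {name!r} must be a non-empty list")

    @property
    def resolved_grid(self) -> dict:
        if self.hyperparameter_grid is not None:
            # accept bare parameter names as well as pipeline-prefixed ones
            return {
                (k if "__" in k else f"clf__{k}"): list(v)
                for k, v in self.hyperparameter_grid.items()
            }
        return DEFAULT_GRIDS[self.algorithm]

    def to_dict(self) -> dict:
        spec = self.fingerprint_spec
        return {
            "algorithm": self.algorithm,
            "fingerprint_spec": {
                "family": spec.family,
                "n_bits": spec.n_bits,
                "radius": spec.radius,
            },
            "hyperparameter_grid": self.hyperparameter_grid,
            "selector_recipe": self.selector_recipe,
            "cv_folds": self.cv_folds,
            "cv_seed": self.cv_seed,
            "selection_metric": self.selection_metric,
            "class_weighting": self.class_weighting,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelConfig":
        doc = dict(doc)
        spec = doc.get("fingerprint_spec")
        if isinstance(spec, dict):
            doc["fingerprint_spec"] = AtomFingerprintSpec(
                family=spec["family"], n_bits=int(spec["n_bits"]),
                radius=spec.get("radius"),
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown model-config fields: {sorted(unknown)}")
        return cls(**doc)


def _make_classifier(config: ModelConfig):
    weight = "balanced" if config.class_weighting else None
    if config.algorithm == "SVM":
        return SVC(class_weight=weight, random_state=config.cv_seed)
    if config.algorithm == "RF":
        return RandomForestClassifier(
            class_weight=weight, random_state=config.cv_seed, n_jobs=1
        )
    return GradientBoostingClassifier(random_state=config.cv_seed)


def _make_selector_step(recipe: dict):
    method = recipe.get("method")
    if method == "VT":
        return VarianceThreshold(threshold=recipe.get("threshold", 0.0))
    if method == "SPF":
        return TopPercentileSelector(
            percentile=recipe.get("percentile", 15.0),
            score_func=recipe.get("score_func", "chi2"),
        )
    if method == "PCA":
        return _SignFixedPCA(n_components=recipe.get("n_components", 128))
    raise ConfigError(f"unknown selector method {method!r} (use VT, SPF, or PCA)")


def build_pipeline(config: ModelConfig) -> Pipeline:
    steps = [
        (f"sel{i}_{r['method'].lower()}", _make_selector_step(r))
        for i, r in enumerate(config.selector_recipe)
    ]
    steps.append(("clf", _make_classifier(config)))
    return Pipeline(steps)


@dataclass
class TrainedSomModel:
    """A frozen, reloadable bundle: recipe + fitted pipeline + threshold."""

    config: ModelConfig
    pipeline: Pipeline = field(repr=False)
    chosen_hyperparameters: dict = field(default_factory=dict)
    cv_report: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    best_cv_score: float = float("nan")
    decision_threshold: float = 0.5

    def score_sites(self, X: np.ndarray) -> np.ndarray:
        """Positive-class scores in [0, 1] for a feature matrix."""
        if hasattr(self.pipeline, "predict_proba") and hasattr(
            self.pipeline.named_steps["clf"], "predict_proba"
        ):
            return self.pipeline.predict_proba(X)[:, 1]
        raw = self.pipeline.decision_function(X)
        return 1.0 / (1.0 + np.exp(-raw))  # monotone squash; rank-identical to raw


@dataclass
class RankedPrediction:
    """Score-ranked candidate atoms of one molecule."""

    molecule: StandardMolecule
    ranked_sites: list[tuple[int, float]]  # (atom_index, score), score descending
    is_predicted_substrate: bool

    def top(self, k: int) -> list[int]:
        return [idx for idx, _ in self.ranked_sites[:k]]


def cross_validated_grid_search(
    X: np.ndarray, y: np.ndarray, config: ModelConfig
) -> TrainedSomModel:
    """Grid search under seeded, stratified k-fold CV; refit best on all rows.

    Ties between grid points resolve to the first point in deterministic grid
    order, so identical inputs and seed give identical chosen parameters and
    an identical per-fold report.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("training labels contain a single class")
    if len(y) < config.cv_folds:
        raise StratificationError(
            f"{len(y)} rows cannot populate {config.cv_folds} folds"
        )
    if counts.min() < config.cv_folds:
        raise StratificationError(
            f"minority class has {counts.min()} rows; every one of the "
            f"{config.cv_folds} stratified folds needs at least one"
        )

    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.cv_seed)
    search = GridSearchCV(
        build_pipeline(config),
        param_grid=config.resolved_grid,
        scoring=_METRIC_ALIASES[config.selection_metric],
        cv=cv,
        refit=True,
        error_score="raise",
        n_jobs=1,
    )
    try:
        search.fit(X, y)
    except ValueError as exc:
        raise NumericError(f"grid search failed: {exc}") from exc

    res = search.cv_results_
    rows = []
    for i, params in enumerate(res["params"]):
        if math.isnan(res["mean_test_score"][i]):
            raise NumericError(f"NaN CV score at grid point {params}")
        for fold in range(config.cv_folds):
            rows.append(
                {
                    "grid_index": i,
                    "params": str(params),
                    "fold": fold,
                    "score": res[f"split{fold}_test_score"][i],
                }
            )
    report = pd.DataFrame(rows)

    chosen = {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
    return TrainedSomModel(
        config=config,
        pipeline=search.best_estimator_,
        chosen_hyperparameters=chosen,
        cv_report=report,
        best_cv_score=float(search.best_score_),
    )


def rank_sites(
    model: TrainedSomModel,
    mol: StandardMolecule,
    definitions: Optional[Sequence[SiteTypeDefinition]] = None,
) -> RankedPrediction:
    """Enumerate, featurize, and score one molecule's candidate atoms.

    A molecule with no candidate site is returned with an empty ranking and
    flagged as a predicted non-substrate.
    """
    sites = enumerate_candidate_sites(mol, definitions=definitions)
    if not sites:
        return RankedPrediction(mol, [], is_predicted_substrate=False)
    spec = model.config.fingerprint_spec
    X = np.stack([featurize_site(mol, s.atom_index, spec).bits for s in sites])
    scores = model.score_sites(X)
    order = sorted(range(len(sites)), key=lambda i: (-scores[i], sites[i].atom_index))
    ranked = [(sites[i].atom_index, float(scores[i])) for i in order]
    return RankedPrediction(mol, ranked, is_predicted_substrate=True)


_ARCHIVE_FORMAT = 1


def persist_model(model: TrainedSomModel, path: Union[str, Path]) -> None:
    """Write a reloadable archive embedding recipe, seed, and version stamps."""
    payload = {
        "archive_format": _ARCHIVE_FORMAT,
        "package_version": _pkg_version,
        "sklearn_version": sklearn.__version__,
        "config": model.config.to_dict(),
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path: Union[str, Path]) -> TrainedSomModel:
    """Reload an archive; predictions equal the in-memory model's exactly."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelArchiveError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or "archive_format" not in payload:
        raise ModelArchiveError(f"{path} is not an aoxsom model archive")
    if payload["archive_format"] != _ARCHIVE_FORMAT:
        raise ModelArchiveError(
            f"archive format {payload['archive_format']} unsupported "
            f"(this package writes format {_ARCHIVE_FORMAT})"
        )
    if payload["sklearn_version"] != sklearn.__version__:
        raise ModelArchiveError(
            f"archive written with scikit-learn {payload['sklearn_version']}, "
            f"running {sklearn.__version__}; retrain or match versions"
        )
    return payload["model"]
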