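"""Gradient-boosted tree models for ddG regression and disruption classification.

Two tasks share one training protocol:

* ``regression`` -- predict the binding free energy change (ddG, kcal/mol)
  of a point mutation; positive output means destabilized binding;
* ``classification`` -- predict whether a mutation is disruptive (abolishes
  detectable complex formation) or non-disruptive.

The protocol repeats a random train/test split ``n_repeats`` times; within
each training portion, hyperparameters are chosen by 5-fold cross-validated
grid search, the model is refit on the whole training portion, and metrics
are measured on the held-out test portion. Reported metrics are means over
repeats (pooled-prediction PCC is also recorded). The returned bundle is
refit on all data with the modal hyperparameters across repeats.

Label-encoded integer features are passed to the trees as ordinal integers;
tree splits make them effectively categorical. Splits randomize over
mutation records, not complexes, so mutations of one complex can appear on
both sides of a split -- a known property of this protocol family, inherited
deliberately (see README).
"""

from __future__ import annotations

import base64
import json
from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .evaluation import ConfusionMatrix, EvalReport, classification_report, pcc_mse
from .featurizer import FEATURE_SCHEMA, FeatureVector

FORMAT_TAG = "ppiddg-model-1"

# Default hyperparameter grid; small and standard, fully overridable.
DEFAULT_GRID: Dict[str, List] = {
    "learning_rate": [0.05, 0.1, 0.3],
    "max_depth": [4, 6, 8],
    "n_estimators": [200, 500],
}

FIXED_PARAMS: Dict[str, object] = {
    "subsample": 0.8,
    "colsample_bytree": 0.8,
    "tree_method": "hist",
    "n_jobs": 1,
}


class SchemaMismatchError(ValueError):
    """Features presented to a model do not match its training schema."""


class TrainingError(ValueError):
    pass


@dataclass
class SplitProtocol:
    """Repeated random-split evaluation protocol."""

    test_fraction: float = 0.2
    n_repeats: int = 100
    cv_folds: int = 5
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class ModelBundle:
    """A trained ensemble plus everything needed to apply and audit it."""

    task: str                                  # "regression" | "classification"
    booster: xgb.Booster
    schema: List[str]
    hyperparameters: Dict[str, object]
    importances: Dict[str, float]              # normalized, sums to 1
    manifest: Dict[str, object] = field(default_factory=dict)

    def _matrix(self, X: np.ndarray | pd.DataFrame | FeatureVector) -> xgb.DMatrix:
        if isinstance(X, FeatureVector):
            if X.schema != self.schema:
                raise SchemaMismatchError("feature-vector schema differs from model schema")
            X = X.values.reshape(1, -1)
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.schema:
                raise SchemaMismatchError("dataframe columns differ from model schema")
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != len(self.schema):
            raise SchemaMismatchError(
                f"expected {len(self.schema)} features, got {X.shape[1]}")
        return xgb.DMatrix(X, feature_names=self.schema)

    def predict(self, X) -> np.ndarray:
        """Raw model output: ddG (regression) or disruption probability."""
        return self.booster.predict(self._matrix(X))

    def save(self, path: Path | str) -> None:
        raw = self.booster.save_raw(raw_format="json")
        payload = {
            "format": FORMAT_TAG,
            "task": self.task,
            "schema": self.schema,
            "hyperparameters": self.hyperparameters,
            "importances": self.importances,
            "manifest": self.manifest,
            "booster_json_b64": base64.b64encode(bytes(raw)).decode("ascii"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: Path | str) -> "ModelBundle":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != FORMAT_TAG:
            raise ValueError(f"not a {FORMAT_TAG} file: {path}")
        booster = xgb.Booster()
        booster.load_model(bytearray(base64.b64decode(payload["booster_json_b64"])))
        return cls(payload["task"], booster, payload["schema"],
                   payload["hyperparameters"], payload["importances"],
                   payload["manifest"])


def _estimator(task: str, params: Dict, seed: int):
    common = dict(FIXED_PARAMS, random_state=seed, **params)
    if task == "regression":
        return xgb.XGBRegressor(**common)
    return xgb.XGBClassifier(eval_metric="logloss", **common)


def _grid_points(grid: Dict[str, List]) -> List[Dict]:
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def _cv_score(task: str, X: np.ndarray, y: np.ndarray, params: Dict,
              folds: int, seed: int) -> float:
    """Mean CV score (higher is better): -MSE for regression, accuracy for classification."""
    splitter = (StratifiedKFold(folds, shuffle=True, random_state=seed)
                if task == "classification"
                else KFold(folds, shuffle=True, random_state=seed))
    scores = []
    for tr, va in splitter.split(X, y):
        est = _estimator(task, params, seed)
        est.fit(X[tr], y[tr])
        if task == "regression":
            pred = est.predict(X[va])
            scores.append(-float(np.mean((pred - y[va]) ** 2)))
        else:
            scores.append(float(np.mean(est.predict(X[va]) == y[va])))
    return float(np.mean(scores))


def _normalized_importances(booster: xgb.Booster, schema: Sequence[str]) -> Dict[str, float]:
    """Gain-based feature importances renormalized to sum exactly to 1.

    Features the ensemble never split on get importance 0.
    """
    raw = booster.get_score(importance_type="gain")
    total = sum(raw.values())
    if total <= 0:
        # constant model: uniform by convention
        return {name: 1.0 / len(schema) for name in schema}
    return {name: raw.get(name, 0.0) / total for name in schema}


def train(features: np.ndarray | pd.DataFrame, targets: Sequence[float],
          task: str = "regression",
          protocol: SplitProtocol = SplitProtocol(),
          schema: Optional[List[str]] = None,
          param_grid: Optional[Dict[str, List]] = None,
          ) -> Tuple[ModelBundle, EvalReport, List[EvalReport]]:
    """Run the repeated-split training protocol.

    Parameters
    ----------
    features
        (n, p) matrix; a DataFrame's columns become the schema.
    targets
        ddG values (regression) or 0/1 disruption labels (classification).
    schema
        Feature names when ``features`` is a bare array; defaults to the
        standard 33-name schema when p matches it.
    param_grid
        Hyperparameter grid searched by k-fold CV inside every repeat;
        defaults to :data:`DEFAULT_GRID`.

    Returns
    -------
    (bundle, report, per_repeat)
        ``bundle`` is refit on all data with the modal hyperparameters;
        ``report`` holds metric means over repeats (plus pooled-prediction
        PCC in ``extras``); ``per_repeat`` the individual test-set reports.
    """
    if isinstance(features, pd.DataFrame):
        schema = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if schema is None:
            if X.shape[1] != len(FEATURE_SCHEMA):
                raise TrainingError("schema required for non-standard feature width")
            schema = list(FEATURE_SCHEMA)
    y = np.asarray(targets, dtype=float)
    if task not in ("regression", "classification"):
        raise TrainingError(f"unknown task {task!r}")
    if len(X) < 50:
        raise TrainingError("training needs at least 50 rows")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise TrainingError("features/targets contain non-finite values")
    if task == "regression" and np.ptp(y) == 0:
        raise TrainingError("constant regression targets: PCC undefined")
    if task == "classification":
        y = y.astype(int)
        if len(np.unique(y)) < 2:
            raise TrainingError("classification needs both classes present")

    grid = _grid_points(param_grid or DEFAULT_GRID)
    per_repeat: List[EvalReport] = []
    chosen: List[Tuple] = []
    pooled_pred: List[np.ndarray] = []
    pooled_obs: List[np.ndarray] = []

    for r in range(protocol.n_repeats):
        seed = protocol.base_seed + r
        stratify = y if task == "classification" else None
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=protocol.test_fraction, random_state=seed,
            stratify=stratify)
        if len(grid) == 1:
            best = grid[0]
        else:
            scored = [(-_cv_score(task, X_tr, y_tr, p, protocol.cv_folds, seed), i)
                      for i, p in enumerate(grid)]
            best = grid[min(scored)[1]]  # ties -> earliest grid point
        chosen.append(tuple(sorted(best.items())))
        est = _estimator(task, best, seed)
        est.fit(X_tr, y_tr)

        if task == "regression":
            pred = est.predict(X_te).astype(float)
            r_val, mse = pcc_mse(pred, y_te)
            per_repeat.append(EvalReport(pcc=r_val, mse=mse, n=len(y_te)))
        else:
            prob = est.predict_proba(X_te)[:, 1]
            per_repeat.append(classification_report(prob, y_te))
            pred = prob
        pooled_pred.append(pred)
        pooled_obs.append(y_te.astype(float))

    modal = dict(Counter(chosen).most_common(1)[0][0])
    final = _estimator(task, modal, protocol.base_seed)
    Xdf = pd.DataFrame(X, columns=schema)
    final.fit(Xdf, y)
    booster = final.get_booster()
    importances = _normalized_importances(booster, schema)

    bundle = ModelBundle(
        task=task, booster=booster, schema=schema,
        hyperparameters=dict(FIXED_PARAMS, **modal),
        importances=importances,
        manifest={
            "n_rows": int(len(X)),
            "base_seed": protocol.base_seed,
            "n_repeats": protocol.n_repeats,
            "test_fraction": protocol.test_fraction,
            "cv_folds": protocol.cv_folds,
            "data_sha1": _data_hash(X, y),
        })

    report = _aggregate(per_repeat, task)
    all_pred = np.concatenate(pooled_pred)
    all_obs = np.concatenate(pooled_obs)
    if task == "regression":
        pooled_r, pooled_mse = pcc_mse(all_pred, all_obs)
        report.extras["pcc_pooled"] = pooled_r
        report.extras["mse_pooled"] = pooled_mse
    return bundle, report, per_repeat


def _data_hash(X: np.ndarray, y: np.ndarray) -> str:
    import hashlib
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def _aggregate(reports: List[EvalReport], task: str) -> EvalReport:
    def mean_of(name: str) -> Optional[float]:
        vals = [getattr(rep, name) for rep in reports if getattr(rep, name) is not None]
        return float(np.mean(vals)) if vals else None

    agg = EvalReport(n=int(np.sum([rep.n for rep in reports])))
    for name in ("pcc", "mse", "auc", "sensitivity", "specificity",
                 "precision", "accuracy", "mcc"):
        setattr(agg, name, mean_of(name))
    if task == "classification":
        cms = [rep.confusion for rep in reports if rep.confusion is not None]
        if cms:
            agg.confusion = ConfusionMatrix(
                tp=sum(c.tp for c in cms), tn=sum(c.tn for c in cms),
                fp=sum(c.fp for c in cms), fn=sum(c.fn for c in cms))
    return agg


def predict_ddg(bundle: ModelBundle, fv: FeatureVector | np.ndarray) -> float | np.ndarray:
    """Predicted ddG (kcal/mol) for one feature vector or a batch.

    Positive output = destabilizing, negative = stabilizing.
    """
    if bundle.task != "regression":
        raise SchemaMismatchError("predict_ddg needs a regression bundle")
    out = bundle.predict(fv)
    return float(out[0]) if out.shape == (1,) else out


def predict_dn(bundle: ModelBundle, fv: FeatureVector | np.ndarray,
               threshold: float = 0.5) -> Tuple[float, str] | Tuple[np.ndarray, List[str]]:
    """Disruption probability and class call for one vector or a batch.

    Class is ``"disruptive"`` iff probability >= ``threshold`` (default 0.5).
    """
    if bundle.task != "classification":
        raise SchemaMismatchError("predict_dn needs a classification bundle")
    prob = bundle.predict(fv)
    classes = ["disruptive" if p >= threshold else "non-disruptive" for p in prob]
    if prob.shape == (1,):
        return float(prob[0]), classes[0]
    return prob, classes


def classify_stability(ddg: float, mode: str = "sign",
                       strong_cutoff: float = 1.5) -> str:
    """Categorize a ddG value.

    ``sign`` mode: destabilizing (ddG > 0), stabilizing (ddG < 0), neutral
    (ddG == 0). ``strong`` mode: highly-destabilizing (ddG > cutoff),
    highly-stabilizing (ddG < -cutoff), intermediate otherwise; boundaries
    fall in the weaker class (strict inequalities).
    """
    if not np.isfinite(ddg):
        raise ValueError("ddG must be finite")
    if mode == "sign":
        if ddg > 0:
            return "destabilizing"
        if ddg < 0:
            return "stabilizing"
        return "neutral"
    if mode == "strong":
        if ddg > strong_cutoff:
            return "highly-destabilizing"
        if ddg < -strong_cutoff:
            return "highly-stabilizing"
        return "intermediate"
    raise ValueError(f"unknown mode {mode!r}")
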