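"""Regression and classification metrics for ddG predictors.

Covers the metrics customarily reported for this class of predictor: Pearson
correlation (PCC) and mean squared error for the regression task; ROC/AUC,
sensitivity, specificity, precision, accuracy and the Matthews correlation
coefficient (MCC) for binary classification; plus stratified breakdowns by
mutation class (interface location, alanine vs non-alanine mutant, size
change, externally annotated secondary structure or complex type).

Degenerate cases follow explicit conventions: an MCC whose denominator has a
zero factor is defined as 0; a rate with a zero denominator is reported as
``None`` (undefined), never silently as 0.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

MIN_STRATUM_SIZE = 10


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, pred: Sequence[int], true: Sequence[int]) -> "ConfusionMatrix":
        pred = np.asarray(pred, dtype=bool)
        true = np.asarray(true, dtype=bool)
        return cls(tp=int(np.sum(pred & true)), tn=int(np.sum(~pred & ~true)),
                   fp=int(np.sum(pred & ~true)), fn=int(np.sum(~pred & true)))


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); if any
    factor of the denominator is zero the coefficient is defined as 0 (with
    a warning), the standard convention for degenerate matrices.
    """
    tp, tn, fp, fn = (float(cm.tp), float(cm.tn), float(cm.fp), float(cm.fn))
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        warnings.warn("MCC denominator has a zero factor; returning 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom2)


@dataclass(frozen=True)
class Rates:
    """Sensitivity, specificity, precision, accuracy; None = undefined."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    accuracy: Optional[float]


def rates(cm: ConfusionMatrix) -> Rates:
    """The four standard confusion-matrix rates.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    precision = TP/(TP+FP), accuracy = (TP+TN)/total. A zero denominator
    yields ``None`` rather than an arbitrary value.
    """
    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return Rates(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        precision=ratio(cm.tp, cm.tp + cm.fp),
        accuracy=ratio(cm.tp + cm.tn, cm.total),
    )


def pcc_mse(pred: Sequence[float], obs: Sequence[float]) -> Tuple[Optional[float], float]:
    """Pearson correlation and mean squared error of predictions vs observations.

    PCC is ``None`` (undefined) when the observations are constant.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(pred) < 3:
        raise ValueError("pcc_mse needs two equal-length 1-d arrays of length >= 3")
    mse = float(np.mean((pred - obs) ** 2))
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return None, mse
    r = float(stats.pearsonr(pred, obs).statistic)
    return r, mse


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> Tuple[float, pd.DataFrame]:
    """ROC analysis: area under the curve plus the curve points.

    AUC is computed by trapezoidal integration over all score thresholds and
    equals the Mann-Whitney probability P(score_pos > score_neg) + 0.5
    P(tie). Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC analysis needs both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    area = float(_trapezoid_auc(fpr, tpr))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return area, curve


@dataclass
class EvalReport:
    """Bundle of regression and/or classification metrics.

    Fields irrelevant to the task at hand stay ``None``. ``strata`` maps
    ``"field=value"`` keys to sub-reports (or the string ``"too-small"``).
    """

    pcc: Optional[float] = None
    mse: Optional[float] = None
    auc: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    precision: Optional[float] = None
    accuracy: Optional[float] = None
    mcc: Optional[float] = None
    confusion: Optional[ConfusionMatrix] = None
    n: int = 0
    strata: Dict[str, object] = field(default_factory=dict)
    extras: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["strata"] = {k: (v.to_dict() if isinstance(v, EvalReport) else v)
                       for k, v in self.strata.items()}
        return d

    def to_json(self, path: Optional[Path | str] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        lines = [f"n = {self.n}"]
        for name in ("pcc", "mse", "auc", "sensitivity", "specificity",
                     "precision", "accuracy", "mcc"):
            value = getattr(self, name)
            if value is not None:
                lines.append(f"{name:12s} {value: .4f}")
        if self.confusion is not None:
            cm = self.confusion
            lines.append(f"confusion    TP={cm.tp} TN={cm.tn} FP={cm.fp} FN={cm.fn}")
        for key, sub in self.strata.items():
            if isinstance(sub, EvalReport):
                lines.append(f"[{key}] n={sub.n} pcc={sub.pcc} mse={sub.mse}")
            else:
                lines.append(f"[{key}] {sub}")
        return "\n".join(lines)


def classification_report(scores: Sequence[float], labels: Sequence[int],
                          threshold: float = 0.5) -> EvalReport:
    """Full binary-classification report from scores and 0/1 labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    area, _ = roc_auc(scores, labels)
    cm = ConfusionMatrix.from_labels(scores >= threshold, labels)
    rt = rates(cm)
    return EvalReport(auc=area, sensitivity=rt.sensitivity,
                      specificity=rt.specificity, precision=rt.precision,
                      accuracy=rt.accuracy, mcc=mcc(cm), confusion=cm,
                      n=len(labels))


@dataclass
class StratumLabel:
    """Per-record strata for the breakdown analyses; optional fields may be None."""

    interface: Optional[bool] = None
    mutant_is_alanine: Optional[bool] = None
    size_change: Optional[int] = None          # size-pair label
    secondary_structure: Optional[str] = None  # external annotation
    complex_type: Optional[str] = None         # external annotation


def regression_report(pred: Sequence[float], obs: Sequence[float]) -> EvalReport:
    r, m = pcc_mse(pred, obs)
    return EvalReport(pcc=r, mse=m, n=len(np.asarray(pred)))


def stratified_report(pred: Sequence[float], obs: Sequence[float],
                      strata: Sequence[StratumLabel]) -> EvalReport:
    """Global regression report plus per-stratum sub-reports.

    For every populated stratum field, records sharing a value form a
    stratum; strata smaller than 10 records are flagged ``"too-small"``
    instead of reporting an unstable PCC.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if not (len(pred) == len(obs) == len(strata)):
        raise ValueError("predictions, observations and strata must align")
    report = regression_report(pred, obs)
    for fieldname in ("interface", "mutant_is_alanine", "size_change",
                      "secondary_structure", "complex_type"):
        values = [getattr(s, fieldname) for s in strata]
        for v in sorted({v for v in values if v is not None}, key=str):
            idx = np.array([x == v for x in values])
            key = f"{fieldname}={v}"
            if int(idx.sum()) < MIN_STRATUM_SIZE:
                report.strata[key] = "too-small"
            else:
                report.strata[key] = regression_report(pred[idx], obs[idx])
    return report


def stability_classification_report(pred_ddg: Sequence[float],
                                    obs_ddg: Sequence[float],
                                    mode: str = "sign",
                                    strong_cutoff: float = 1.5) -> EvalReport:
    """Classification view of a ddG regressor's output.

    ``sign`` mode labels records destabilizing (ddG > 0) vs stabilizing
    (ddG < 0); exact zeros carry no sign information and are excluded.
    ``strong`` mode restricts to |ddG| > ``strong_cutoff`` and labels highly
    destabilizing vs highly stabilizing. The predicted ddG serves as the ROC
    score and its sign as the hard class call.
    """
    pred_ddg = np.asarray(pred_ddg, dtype=float)
    obs_ddg = np.asarray(obs_ddg, dtype=float)
    if mode == "sign":
        keep = obs_ddg != 0
    elif mode == "strong":
        keep = np.abs(obs_ddg) > strong_cutoff
    else:
        raise ValueError(f"unknown mode {mode!r}")
    labels = (obs_ddg[keep] > 0).astype(int)
    return classification_report(pred_ddg[keep], labels, threshold=0.0)


def read_strata_tsv(path: Path | str) -> pd.DataFrame:
    """Read an external strata-annotation table.

    Tab-separated with columns ``complex_id chain pos wt mut`` plus any of
    ``secondary_structure`` / ``complex_type``.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    key_cols = ["complex_id", "chain", "pos", "wt", "mut"]
    missing = [c for c in key_cols if c not in df.columns]
    if missing:
        raise ValueError(f"strata annotation lacks key columns {missing}")
    return df


def write_roc_tsv(curve: pd.DataFrame, path: Path | str) -> None:
    curve.to_csv(path, sep="\t", index=False)
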