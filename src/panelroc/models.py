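"""Per-combination logistic models, combi-scores, and classification.

For a selected combination with members x1..xn a binomial GLM is fitted on
the labeled training table:

    f(x) = b0 + b1*x1 + ... + bn*xn,      p(x) = 1 / (1 + exp(-f(x)))

p(x) is the *combi-score*: the predicted probability that a sample (or cell)
belongs to the positive class.  The training scores yield a ROC curve and
its AUC, and an optimal probability cutoff — the candidate cutoff with the
fewest training misclassifications under the rule "predict case iff
score > cutoff" (ties broken by maximal Youden, then lowest cutoff).
Unlabeled samples are classified by C(x): 1 when p(x) > cutoff, 0 when
p(x) <= cutoff.

The GLM itself is fitted with statsmodels (IRLS, 25 iterations, deviance
tolerance 1e-8).  Complete separation is detected and flagged — coefficients
are reported as fitted, with no silent penalization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .combinations import Combination
from .errors import ClassLabelError, DegenerateCutoffError, MarkerMismatchError
from .tables import MarkerTable
from .threshold import ROCCoordinates, candidate_thresholds, roc_from_values

#: |coefficient| beyond which a fit is treated as separated/diverged.
COEF_CAP = 1e2
#: boundary band for fitted probabilities; must be looser than the IRLS
#: deviance stopping tolerance (1e-8), which halts iteration while fitted
#: probabilities are still ~1e-9 from {0,1} under complete separation
PROB_EPS = 1e-6


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class CombinationModel:
    """Fitted logistic model for one marker combination."""

    combination: Combination
    intercept: float
    coefficients: dict[str, float]  # marker -> beta, on the signal scale
    roc: ROCCoordinates
    auc: float
    optimal_cutoff: float
    training_se: float
    training_sp: float
    case_label: str | None = None
    converged: bool = True
    separation_detected: bool = False
    n_iterations: int = 0

    @property
    def members(self) -> tuple[str, ...]:
        return self.combination.members

    def linear_predictor(self, signals: pd.DataFrame) -> np.ndarray:
        beta = np.array([self.coefficients[m] for m in self.members])
        return self.intercept + signals[list(self.members)].to_numpy(float) @ beta

    # -- serialization ---------------------------------------------------------

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "combination_id": self.combination.id,
            "markers": list(self.members),
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "auc": self.auc,
            "optimal_cutoff": self.optimal_cutoff,
            "training_se": self.training_se,
            "training_sp": self.training_sp,
            "case_label": self.case_label,
            "converged": self.converged,
            "separation_detected": self.separation_detected,
            "n_iterations": self.n_iterations,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "CombinationModel":
        """Load from a JSON string or a path to a JSON file (training ROC
        coordinates are not serialized; a degenerate placeholder is used)."""
        try:
            payload = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                payload = json.load(fh)
        empty = np.array([])
        return cls(
            combination=Combination(
                id=int(payload["combination_id"]),
                members=tuple(payload["markers"]),
            ),
            intercept=float(payload["intercept"]),
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            roc=ROCCoordinates(empty, empty, empty, empty),
            auc=float(payload["auc"]),
            optimal_cutoff=float(payload["optimal_cutoff"]),
            training_se=float(payload["training_se"]),
            training_sp=float(payload["training_sp"]),
            case_label=payload.get("case_label"),
            converged=bool(payload.get("converged", True)),
            separation_detected=bool(payload.get("separation_detected", False)),
            n_iterations=int(payload.get("n_iterations", 0)),
        )


@dataclass
class ScoreResult:
    """Per-sample combi-scores and inferred classes for one model."""

    sample_ids: list[str]
    combi_score: np.ndarray  # p(x), in [0, 1]
    predicted_class: np.ndarray  # C(x): 1 = case, 0 = other
    model_id: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ID": self.sample_ids,
                "combi_score": self.combi_score,
                "predicted_class": self.predicted_class,
            }
        )


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    recall_defined: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def roc_auc(scores, labels) -> tuple[ROCCoordinates, float]:
    """Empirical ROC over candidate score cutoffs and its trapezoidal AUC.

    The grid contains every attainable operating point, so the trapezoidal
    area equals the Mann-Whitney pairwise-concordance statistic with ties
    counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    coords = roc_from_values(scores[labels == 1], scores[labels == 0])
    # along ascending thresholds both TPR and FPR are non-increasing, so the
    # coordinates already trace the curve; integrating in that order keeps
    # vertical tie segments intact (re-sorting by FPR would break them)
    fpr = 1.0 - coords.sp
    auc = float(-np.trapezoid(coords.se, fpr))
    return coords, auc


def optimal_cutoff(scores, labels) -> float:
    """Probability cutoff minimizing training misclassifications.

    Candidates are midpoints between consecutive distinct scores; prediction
    rule is "case iff score > cutoff".  Ties are broken by maximal Youden
    index, then by the lowest cutoff.  Raises when all scores are identical.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ClassLabelError("both classes must be present to choose a cutoff")
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise DegenerateCutoffError("all scores identical; cutoff undefined")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    case = np.sort(scores[labels == 1])
    control = np.sort(scores[labels == 0])
    # errors(c) = #cases <= c  +  #controls > c
    fn = np.searchsorted(case, candidates, side="right")
    fp = control.size - np.searchsorted(control, candidates, side="right")
    errors = fn + fp
    se = 1.0 - fn / case.size
    sp = 1.0 - fp / control.size
    youden = se + sp - 1.0
    best = errors == errors.min()
    best &= youden == youden[best].max()
    return float(candidates[best][0])


def fit_combination_model(
    table: MarkerTable,
    combo: Combination,
    maxiter: int = 25,
    tol: float = 1e-8,
) -> CombinationModel:
    """Fit the binomial GLM for one combination on a labeled table.

    Non-convergence or complete separation never crashes: the model is
    returned with its ``converged``/``separation_detected`` flags set and a
    warning emitted.
    """
    table.require_labeled()
    missing = [m for m in combo.members if m not in table.markers]
    if missing:
        raise MarkerMismatchError(missing)

    y = table.class_binary().to_numpy(dtype=float)
    X = sm.add_constant(
        table.signals[list(combo.members)].to_numpy(dtype=float), has_constant="add"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            maxiter=maxiter, tol=tol, tol_criterion="deviance"
        )
    params = np.asarray(fit.params, dtype=float)
    fitted = np.asarray(fit.fittedvalues, dtype=float)
    converged = bool(getattr(fit, "converged", True))
    separated = bool(
        np.any(np.abs(params) > COEF_CAP)
        or np.all((fitted < PROB_EPS) | (fitted > 1.0 - PROB_EPS))
    )
    if separated or not converged:
        warnings.warn(
            f"model for {combo.label()} "
            + ("shows complete separation" if separated else "did not converge")
            + "; coefficients reported as fitted",
            stacklevel=2,
        )

    roc, auc = roc_auc(fitted, y.astype(int))
    cutoff = optimal_cutoff(fitted, y.astype(int))
    predicted = fitted > cutoff
    is_case = y == 1.0
    training_se = float(np.mean(predicted[is_case]))
    training_sp = float(np.mean(~predicted[~is_case]))

    return CombinationModel(
        combination=combo,
        intercept=float(params[0]),
        coefficients={m: float(b) for m, b in zip(combo.members, params[1:])},
        roc=roc,
        auc=auc,
        optimal_cutoff=cutoff,
        training_se=training_se,
        training_sp=training_sp,
        case_label=table.case_label,
        converged=converged,
        separation_detected=separated,
        n_iterations=int(getattr(fit, "fit_history", {}).get("iteration", 0) or 0),
    )


def combi_score(table: MarkerTable, model: CombinationModel) -> ScoreResult:
    """Score a table (unlabeled is fine) with a fitted model.

    combi_score = p(x); predicted_class = C(x) = 1 iff p(x) strictly exceeds
    the model's optimal cutoff (a score exactly at the cutoff is class 0).
    """
    missing = [m for m in model.members if m not in table.markers]
    if missing:
        raise MarkerMismatchError(missing)
    p = sigmoid(model.linear_predictor(table.signals))
    return ScoreResult(
        sample_ids=table.sample_ids,
        combi_score=np.asarray(p, dtype=float),
        predicted_class=(p > model.optimal_cutoff).astype(int),
        model_id=model.combination.id,
    )


def evaluate_classification(predicted, truth) -> ClassificationReport:
    """Confusion counts plus precision/recall/F1/accuracy of the case class.

    With no positive truth samples, recall (and F1) are reported as 0 with
    ``recall_defined=False``.
    """
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall_defined = (tp + fn) > 0
    recall = tp / (tp + fn) if recall_defined else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    accuracy = (tp + tn) / predicted.size
    return ClassificationReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        recall_defined=recall_defined,
    )


def cluster_median_scores(
    result: ScoreResult, cluster_labels: pd.Series | Sequence[str]
) -> pd.DataFrame:
    """Median combi-score per cluster label (the heatmap/violin summary view):
    columns ``cluster, median_combi_score, n_cells``."""
    labels = pd.Series(cluster_labels)
    if len(labels) != len(result.sample_ids):
        labels = labels.reindex(result.sample_ids)
        if labels.isna().any():
            raise ValueError("cluster labels do not cover all scored samples")
    df = pd.DataFrame({"cluster": labels.to_numpy(), "score": result.combi_score})
    out = (
        df.groupby("cluster", sort=True)["score"]
        .agg(median_combi_score="median", n_cells="size")
        .reset_index()
    )
    return out
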