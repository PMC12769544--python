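"""Global signal-threshold suggestion from pooled per-class distributions.

All markers' signals are pooled into a single case column and a single
control column, and a ROC curve is traced over candidate thresholds.  The
candidate grid is the set of midpoints between consecutive distinct pooled
values, plus one sentinel below the minimum and one above the maximum: with
a strict ``signal > threshold`` positivity rule this grid realises every
attainable (SE, SP) operating point exactly, and it is shift-equivariant.

Two suggestion rules are provided.  ``median_of_qualifying`` returns the
median of all candidate thresholds whose SE and SP meet the user minima;
``max_youden_qualifying`` returns the qualifying threshold with the highest
Youden index (J = SE + SP - 1).  Both are legitimate readings of the
procedure; the median rule is the default.  With min_SE = min_SP = 0 the
median rule degenerates (by design, documented) to the median of all
candidate thresholds.

The kernel-density summary is presentation-only: it never feeds the
suggestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import ClassLabelError, DensityError, ThresholdNotFoundError

logger = logging.getLogger(__name__)

SuggestionMode = Literal["median_of_qualifying", "max_youden_qualifying"]


@dataclass
class ROCCoordinates:
    """Per-candidate-threshold sensitivity/specificity table.

    SE is non-increasing and SP non-decreasing along ascending thresholds;
    ``youden`` is SE + SP - 1 at each coordinate.  Values are fractions;
    multiply by 100 for percent-scale display.
    """

    thresholds: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    youden: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "se": self.se,
                "sp": self.sp,
                "youden": self.youden,
            }
        )


@dataclass
class ThresholdSuggestion:
    suggested_threshold: float
    min_se: float
    min_sp: float
    qualifying_count: int
    mode: SuggestionMode


@dataclass
class DensitySummary:
    """Per-class Gaussian KDE curves over the pooled signals, on a shared
    grid, for the classic overlapping-distributions plot."""

    grid: np.ndarray
    densities: dict[str, np.ndarray]
    bandwidths: dict[str, float]
    suggestion: float | None = None

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"class": label, "grid": self.grid, "density": dens})
            for label, dens in self.densities.items()
        ]
        return pd.concat(frames, ignore_index=True)


def candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct values, plus one sentinel below
    the minimum and one above the maximum."""
    distinct = np.unique(np.asarray(values, dtype=float))
    if distinct.size == 0:
        raise ValueError("no signal values")
    if distinct.size == 1:
        pad = 0.5
        return np.array([distinct[0] - pad, distinct[0] + pad])
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    pad = float(np.mean(np.diff(distinct))) / 2.0
    return np.concatenate([[distinct[0] - pad], mids, [distinct[-1] + pad]])


def roc_from_values(case_values, control_values) -> ROCCoordinates:
    """Exact empirical ROC for the rule "positive iff value > threshold".

    SE(t) = fraction of case values above t; SP(t) = fraction of control
    values at or below t.  Evaluated on the midpoint candidate grid over the
    pooled values.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ClassLabelError("both classes must be present")
    thr = candidate_thresholds(np.concatenate([case, control]))
    case_sorted = np.sort(case)
    control_sorted = np.sort(control)
    # integer counts first so fractions match a per-sample recount exactly
    se = (case.size - np.searchsorted(case_sorted, thr, side="right")) / case.size
    sp = np.searchsorted(control_sorted, thr, side="right") / control.size
    return ROCCoordinates(thresholds=thr, se=se, sp=sp, youden=se + sp - 1.0)


def pooled_roc_coordinates(long_records: pd.DataFrame, case_class: str) -> ROCCoordinates:
    """ROC coordinates over the pooled single-marker signals of a long-form
    labeled table (columns ``class`` and ``signal``)."""
    classes = long_records["class"].to_numpy()
    present = set(np.unique(classes))
    if case_class not in present or len(present) < 2:
        raise ClassLabelError(
            f"need case class {case_class!r} plus at least one other class; "
            f"found {sorted(map(str, present))}"
        )
    signals = long_records["signal"].to_numpy(dtype=float)
    is_case = classes == case_class
    return roc_from_values(signals[is_case], signals[~is_case])


def suggest_signal_threshold(
    coords: ROCCoordinates,
    min_se: float = 0.0,
    min_sp: float = 0.0,
    mode: SuggestionMode = "median_of_qualifying",
) -> ThresholdSuggestion:
    """Suggest the global signal-positivity threshold from ROC coordinates.

    Raises :class:`ThresholdNotFoundError` when no candidate threshold meets
    both minima — never a silent fallback.
    """
    qualifying = (coords.se >= min_se) & (coords.sp >= min_sp)
    count = int(qualifying.sum())
    if count == 0:
        raise ThresholdNotFoundError(
            f"no threshold satisfies constraints min_se={min_se}, min_sp={min_sp}"
        )
    q_thr = coords.thresholds[qualifying]
    if mode == "median_of_qualifying":
        value = float(np.median(q_thr))
    elif mode == "max_youden_qualifying":
        q_youden = coords.youden[qualifying]
        value = float(q_thr[int(np.argmax(q_youden))])
    else:
        raise ValueError(f"unknown suggestion mode {mode!r}")
    # flag when the two readings of the rule disagree materially
    other = "max_youden_qualifying" if mode == "median_of_qualifying" else "median_of_qualifying"
    alt = (
        float(np.median(q_thr))
        if other == "median_of_qualifying"
        else float(q_thr[int(np.argmax(coords.youden[qualifying]))])
    )
    step = float(np.median(np.diff(coords.thresholds))) if coords.thresholds.size > 1 else 0.0
    if abs(alt - value) > step:
        logger.info(
            "suggestion modes differ: %s=%.6g vs %s=%.6g", mode, value, other, alt
        )
    return ThresholdSuggestion(
        suggested_threshold=value,
        min_se=min_se,
        min_sp=min_sp,
        qualifying_count=count,
        mode=mode,
    )


def density_summary(
    long_records: pd.DataFrame,
    bandwidth_rule: str | float = "silverman",
    gridsize: int = 512,
    suggestion: float | None = None,
) -> DensitySummary:
    """Per-class Gaussian KDE of pooled signals on a shared grid spanning the
    pooled range (padded by three bandwidths so curves integrate to ~1)."""
    classes = long_records["class"].to_numpy()
    signals = long_records["signal"].to_numpy(dtype=float)
    labels = list(pd.unique(long_records["class"]))
    kdes: dict[str, gaussian_kde] = {}
    bandwidths: dict[str, float] = {}
    for label in labels:
        vals = signals[classes == label]
        if np.unique(vals).size < 2:
            raise DensityError(f"class {label!r} has degenerate (all-equal) signals")
        kde = gaussian_kde(vals, bw_method=bandwidth_rule)
        kdes[label] = kde
        bandwidths[label] = float(np.sqrt(kde.covariance[0, 0]))
    pad = 3.0 * max(bandwidths.values())
    grid = np.linspace(signals.min() - pad, signals.max() + pad, gridsize)
    densities = {label: kde(grid) for label, kde in kdes.items()}
    return DensitySummary(
        grid=grid, densities=densities, bandwidths=bandwidths, suggestion=suggestion
    )


def export_density_plot(summary: DensitySummary, path: str) -> None:
    """Write the overlapping per-class density plot, with the suggested
    threshold as a dashed vertical line, to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, dens in summary.densities.items():
        ax.plot(summary.grid, dens, label=str(label))
        ax.fill_between(summary.grid, dens, alpha=0.2)
    if summary.suggestion is not None:
        ax.axvline(summary.suggestion, color="black", linestyle="--")
        ax.annotate(
            f"{summary.suggestion:g}",
            xy=(summary.suggestion, ax.get_ylim()[1] * 0.95),
            ha="left",
        )
    ax.set_xlabel("signal")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
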