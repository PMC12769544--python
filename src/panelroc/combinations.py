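"""Exhaustive enumeration and scoring of marker combinations.

A sample is *positive* for a combination when at least ``combithr`` of the
combination's markers have a signal strictly above ``signalthr`` — the same
strict ">" convention used by the threshold finder.  Each combination is
scored by sensitivity (positive fraction among cases), specificity (negative
fraction among controls) and the Youden index J = SE + SP - 1, then ranked.

Enumeration order is deterministic: ascending combination length, then
lexicographic over the alphabetically sorted marker names; IDs are assigned
1..N in that order.  The order is a documented convention of this package —
combination IDs are not comparable across implementations, so combinations
should be matched by their member sets.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .tables import MarkerTable

#: Columns of the stats table produced by :func:`evaluate_combinations`.
STATS_COLUMNS = [
    "id",
    "markers",
    "length",
    "positives_case",
    "positives_control",
    "se",
    "sp",
    "youden",
]


@dataclass(frozen=True)
class Combination:
    """One enumerated marker combination: 1-based ID, sorted member tuple."""

    id: int
    members: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.members)

    def label(self) -> str:
        return "|".join(self.members)


def count_combinations(n_markers: int, max_length: int) -> int:
    """Closed-form count of combinations of 1..max_length markers out of
    n_markers: sum over k of C(n, k).  (30, 5) -> 174,436."""
    if not 1 <= max_length <= n_markers:
        raise ArgumentError(
            f"max_length must be in [1, n_markers]; got {max_length} with "
            f"{n_markers} markers"
        )
    return sum(math.comb(n_markers, k) for k in range(1, max_length + 1))


def iter_combinations(markers: Sequence[str], max_length: int) -> Iterator[Combination]:
    """Lazily enumerate combinations in the canonical deterministic order."""
    if len(set(markers)) != len(markers):
        raise ArgumentError("marker names must be unique")
    if not 1 <= max_length <= len(markers):
        raise ArgumentError(
            f"max_length must be in [1, {len(markers)}]; got {max_length}"
        )
    ordered = sorted(markers)
    combo_id = 0
    for length in range(1, max_length + 1):
        for members in itertools.combinations(ordered, length):
            combo_id += 1
            yield Combination(id=combo_id, members=members)


def enumerate_combinations(markers: Sequence[str], max_length: int) -> list[Combination]:
    """Materialized :func:`iter_combinations`; length always equals
    :func:`count_combinations`."""
    return list(iter_combinations(markers, max_length))


def sample_positive(
    signals: Mapping[str, float],
    combo: Combination,
    signalthr: float,
    combithr: int = 1,
) -> bool:
    """Positivity rule for a single sample: at least ``combithr`` member
    markers strictly above ``signalthr``.  A signal exactly equal to the
    threshold does NOT count as above."""
    if not 1 <= combithr <= combo.length:
        raise ArgumentError(
            f"combithr must be in [1, {combo.length}]; got {combithr}"
        )
    missing = [m for m in combo.members if m not in signals]
    if missing:
        raise ArgumentError(f"markers absent from sample: {', '.join(missing)}")
    above = sum(1 for m in combo.members if signals[m] > signalthr)
    return above >= combithr


def evaluate_combinations(
    table: MarkerTable,
    signalthr: float,
    combithr: int = 1,
    max_length: int = 3,
) -> pd.DataFrame:
    """Score every combination up to ``max_length`` on a labeled table.

    Returns one row per combination (columns :data:`STATS_COLUMNS`), with
    SE computed on the case class and SP on the control class.  The
    per-marker positivity matrix is computed once; combinations are then
    evaluated in a streaming pass without materializing per-sample masks for
    all combinations at once.  ``signalthr``/``combithr`` are recorded in
    ``DataFrame.attrs``.
    """
    table.require_labeled()
    if combithr < 1:
        raise ArgumentError(f"combithr must be >= 1; got {combithr}")

    is_case = table.class_binary().to_numpy(dtype=bool)
    n_case = int(is_case.sum())
    n_control = int((~is_case).sum())
    above = table.signals.to_numpy(dtype=float) > signalthr  # samples x markers
    col_of = {m: j for j, m in enumerate(table.markers)}

    rows = []
    for combo in iter_combinations(table.markers, max_length):
        if combithr > combo.length:
            # short combinations cannot reach combithr positives
            pos_case = pos_control = 0
        else:
            idx = [col_of[m] for m in combo.members]
            positive = above[:, idx].sum(axis=1) >= combithr
            pos_case = int(np.count_nonzero(positive & is_case))
            pos_control = int(np.count_nonzero(positive & ~is_case))
        se = pos_case / n_case
        sp = 1.0 - pos_control / n_control
        rows.append(
            (
                combo.id,
                combo.label(),
                combo.length,
                pos_case,
                pos_control,
                se,
                sp,
                se + sp - 1.0,
            )
        )

    stats = pd.DataFrame(rows, columns=STATS_COLUMNS)
    stats.attrs["signalthr"] = signalthr
    stats.attrs["combithr"] = combithr
    stats.attrs["n_case"] = n_case
    stats.attrs["n_control"] = n_control
    return stats


def rank_combinations(
    stats: pd.DataFrame, min_se: float = 0.0, min_sp: float = 0.0
) -> pd.DataFrame:
    """Filter by SE/SP minima and rank by descending Youden index.

    Ties are broken by shorter combination length, then smaller ID, so the
    ranking is fully deterministic.  Returns a copy with a 1-based ``rank``
    column; empty (with a warning) when nothing survives the filter.
    """
    if stats.empty:
        raise ArgumentError("stats table is empty")
    survivors = stats[(stats["se"] >= min_se) & (stats["sp"] >= min_sp)].copy()
    if survivors.empty:
        warnings.warn(
            f"no combination satisfies min_se={min_se}, min_sp={min_sp}",
            stacklevel=2,
        )
        out = survivors.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    survivors = survivors.sort_values(
        by=["youden", "length", "id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    survivors.insert(0, "rank", np.arange(1, len(survivors) + 1))
    return survivors


def members_of(stats_row: pd.Series | Mapping) -> tuple[str, ...]:
    """Recover the member tuple from a stats/ranked table row."""
    return tuple(str(stats_row["markers"]).split("|"))
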