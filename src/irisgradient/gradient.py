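"""Dorsoventral and temporal fold-change classification.

Each transcript carries four RPKM values (v4, d4, v8, d8: ventral/dorsal
iris at 4 and 8 days post-lentectomy).  Three log2 fold changes summarise
the dorsoventral gradient:

    log2Fc4 = log2(d4 / v4)                      (per-day ratio, 4 dpl)
    log2Fc8 = log2(d8 / v8)                      (per-day ratio, 8 dpl)
    log2Fc  = log2((d4 + d8) / (v4 + v8))        (combined ranking statistic)

A ratio is UNDEFINED (NaN here, printed "NA") when either operand is zero;
the combined statistic stays defined as long as each side has nonzero RPKM
on at least one day.  Classification:

* ``dorsal_exclusive`` — zero ventral *read counts* on both days (RPKM == 0
  exactly when the count is 0) with dorsal RPKM above the detection cutoff
  on both days; symmetric for ``ventral_exclusive``.
* ``dorsal_up`` / ``ventral_up`` — expressed above the cutoff on the
  up-regulated side on both days, with the per-day ratio beyond the fold
  threshold on both days.  A zero-RPKM denominator with an expressed
  numerator passes any threshold (the ratio diverges).
* ``unclassified`` otherwise.

Temporal classification (day4_up / day8_up) requires the day-of-interest
expression above cutoff on *both* sides and a strictly-greater-than fold
on both sides, mirroring the "more than 2-fold in both dorsal and ventral"
workflow; the dorsoventral workflow's "at least 2-fold" is inclusive by
default.  Both thresholds are configurable.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .cutoffs import CutoffSet
from .quantify import ExpressionTable

DV_CLASSES = (
    "dorsal_up",
    "ventral_up",
    "dorsal_exclusive",
    "ventral_exclusive",
    "unclassified",
)

DAY_CLASSES = ("day4_up", "day8_up", "neither")


def log2_fold_change(numerator_rpkm: float, denominator_rpkm: float) -> float:
    """log2(numerator/denominator); NaN when either side is zero."""
    if numerator_rpkm < 0 or denominator_rpkm < 0:
        raise ValueError("RPKM values must be non-negative")
    if numerator_rpkm == 0 or denominator_rpkm == 0:
        return math.nan
    return math.log2(numerator_rpkm / denominator_rpkm)


def combined_log2_fold_change(d4: float, d8: float, v4: float, v8: float) -> float:
    """log2 of summed dorsal over summed ventral RPKM across both days.

    Defined whenever both sums are positive, so a single zero day on one
    side does not undefine the statistic (unlike the per-day ratios).
    """
    if min(d4, d8, v4, v8) < 0:
        raise ValueError("RPKM values must be non-negative")
    dorsal, ventral = d4 + d8, v4 + v8
    if dorsal == 0 or ventral == 0:
        return math.nan
    return math.log2(dorsal / ventral)


def _fold_passes(num: float, den: float, threshold: float, inclusive: bool) -> bool:
    # zero denominator with expressed numerator: ratio diverges, passes
    if num == 0:
        return False
    if den == 0:
        return True
    ratio = num / den
    return ratio >= threshold if inclusive else ratio > threshold


def classify_dorsoventral(
    counts: Mapping[str, int],
    rpkm: Mapping[str, float],
    cutoffs: CutoffSet,
    fold_threshold: float = 2.0,
    inclusive: bool = True,
    require_both_sides: bool = False,
) -> str:
    """Dorsoventral class of one transcript.

    Parameters
    ----------
    counts, rpkm:
        Per-condition read counts and RPKM values (keys 4dv, 4dd, 8dv, 8dd).
    cutoffs:
        Per-condition detection thresholds.
    fold_threshold:
        Per-day dorsal/ventral (or ventral/dorsal) ratio required on both
        days; must exceed 1.
    inclusive:
        Whether the ratio comparison is ``>=`` (default, "at least") or
        strict ``>``.
    require_both_sides:
        When true, the down-regulated side must also be expressed above its
        cutoff for an ``*_up`` call (never for exclusivity, which demands
        the opposite side at zero).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    missing = [c for c in ("4dv", "4dd", "8dv", "8dd") if c not in rpkm or c not in counts]
    if missing:
        raise KeyError(f"missing conditions {missing}")
    v4, d4 = rpkm["4dv"], rpkm["4dd"]
    v8, d8 = rpkm["8dv"], rpkm["8dd"]
    dorsal_expr = d4 > cutoffs["4dd"] and d8 > cutoffs["8dd"]
    ventral_expr = v4 > cutoffs["4dv"] and v8 > cutoffs["8dv"]

    if counts["4dv"] == 0 and counts["8dv"] == 0 and dorsal_expr:
        return "dorsal_exclusive"
    if counts["4dd"] == 0 and counts["8dd"] == 0 and ventral_expr:
        return "ventral_exclusive"

    if (
        dorsal_expr
        and (ventral_expr or not require_both_sides)
        and _fold_passes(d4, v4, fold_threshold, inclusive)
        and _fold_passes(d8, v8, fold_threshold, inclusive)
    ):
        return "dorsal_up"
    if (
        ventral_expr
        and (dorsal_expr or not require_both_sides)
        and _fold_passes(v4, d4, fold_threshold, inclusive)
        and _fold_passes(v8, d8, fold_threshold, inclusive)
    ):
        return "ventral_up"
    return "unclassified"


def classify_temporal(
    rpkm: Mapping[str, float],
    cutoffs: CutoffSet,
    fold_threshold: float = 2.0,
    direction: str = "day4_vs_day8",
) -> str:
    """Temporal class of one transcript for one comparison direction.

    ``day4_vs_day8`` tests for ``day4_up``: expressed above the cutoff in
    both 4 dpl libraries and strictly more than ``fold_threshold``-fold up
    relative to 8 dpl on *both* sides.  ``day8_vs_day4`` is symmetric.
    Returns the day class or ``"neither"``.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if direction not in ("day4_vs_day8", "day8_vs_day4"):
        raise ValueError(f"unknown direction {direction!r}")
    missing = [c for c in ("4dv", "4dd", "8dv", "8dd") if c not in rpkm]
    if missing:
        raise KeyError(f"missing conditions {missing}")
    v4, d4 = rpkm["4dv"], rpkm["4dd"]
    v8, d8 = rpkm["8dv"], rpkm["8dd"]
    if direction == "day4_vs_day8":
        expressed = d4 > cutoffs["4dd"] and v4 > cutoffs["4dv"]
        folds = _fold_passes(d4, d8, fold_threshold, False) and _fold_passes(
            v4, v8, fold_threshold, False
        )
        return "day4_up" if expressed and folds else "neither"
    expressed = d8 > cutoffs["8dd"] and v8 > cutoffs["8dv"]
    folds = _fold_passes(d8, d4, fold_threshold, False) and _fold_passes(
        v8, v4, fold_threshold, False
    )
    return "day8_up" if expressed and folds else "neither"


def _log2_ratio_or_nan(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = (num > 0) & (den > 0)
    out[ok] = np.log2(num[ok] / den[ok])
    return out


def build_gradient_table(
    expression: ExpressionTable,
    cutoffs: CutoffSet,
    fold_threshold: float = 2.0,
    inclusive: bool = True,
    require_both_sides: bool = False,
) -> pd.DataFrame:
    """Per-transcript fold-change record, ranked by the combined statistic.

    Returns a DataFrame indexed by transcript id with columns ``v4, d4, v8,
    d8`` (RPKM), ``log2fc4, log2fc8, log2fc`` (NaN when undefined) and
    ``dv_class``, sorted by descending combined log2 fold change with NaN
    rows last and ties broken by transcript id.
    """
    rp = expression.rpkm
    v4 = rp["4dv"].to_numpy(float)
    d4 = rp["4dd"].to_numpy(float)
    v8 = rp["8dv"].to_numpy(float)
    d8 = rp["8dd"].to_numpy(float)

    fc4 = _log2_ratio_or_nan(d4, v4)
    fc8 = _log2_ratio_or_nan(d8, v8)
    fc = _log2_ratio_or_nan(d4 + d8, v4 + v8)

    classes = [
        classify_dorsoventral(
            expression.counts.loc[tid].to_dict(),
            rp.loc[tid].to_dict(),
            cutoffs,
            fold_threshold=fold_threshold,
            inclusive=inclusive,
            require_both_sides=require_both_sides,
        )
        for tid in rp.index
    ]
    table = pd.DataFrame(
        {
            "v4": v4,
            "d4": d4,
            "v8": v8,
            "d8": d8,
            "log2fc4": fc4,
            "log2fc8": fc8,
            "log2fc": fc,
            "dv_class": classes,
        },
        index=rp.index,
    )
    return (
        table.reset_index()
        .sort_values(["log2fc", "transcript_id"], ascending=[False, True], na_position="last")
        .set_index("transcript_id")
    )


def build_temporal_table(
    expression: ExpressionTable,
    cutoffs: CutoffSet,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-transcript day classification with per-side temporal log2 ratios.

    A transcript is ``day4_up`` or ``day8_up`` per :func:`classify_temporal`
    (the two calls cannot both fire for ``fold_threshold`` > 1), otherwise
    ``neither``.
    """
    rp = expression.rpkm
    records = []
    for tid, row in rp.iterrows():
        r = row.to_dict()
        cls = classify_temporal(r, cutoffs, fold_threshold, "day4_vs_day8")
        if cls == "neither":
            cls = classify_temporal(r, cutoffs, fold_threshold, "day8_vs_day4")
        records.append(
            {
                "transcript_id": tid,
                "log2_dorsal_d4_over_d8": log2_fold_change(r["4dd"], r["8dd"]),
                "log2_ventral_d4_over_d8": log2_fold_change(r["4dv"], r["8dv"]),
                "day_class": cls,
            }
        )
    return pd.DataFrame.from_records(records).set_index("transcript_id")
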