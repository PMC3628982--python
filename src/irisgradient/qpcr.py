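"""qPCR standard-curve quantification and validation statistics.

A dilution series of known template amounts gives a straight line

    Ct = slope * log10(amount) + intercept

with slope near -1/log10(2) = -3.3219 for perfect doubling each cycle;
amplification efficiency is 10^(-1/slope) - 1.  Unknown samples are
quantified by inverting the line, normalised to a reference (housekeeping)
gene, and compared between iris sides/days with a Levene-gated t-test
(pooled-variance Student when Levene's test for equal variances has
p > 0.05, Welch otherwise) and a balanced two-way side x day ANOVA.

Replicate Ct values are back-transformed to amounts individually and then
averaged — averaging on the Ct (log) scale would estimate the geometric
rather than arithmetic mean amount.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, SampleSizeError, StandardCurveError

#: slope of an ideal (100% efficient) standard curve, Ct per decade
PERFECT_SLOPE = -1.0 / math.log10(2.0)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted Ct-versus-log10(amount) line."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 1.0 = perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def ct(self, log10_amount: float) -> float:
        return self.slope * log10_amount + self.intercept


class LeveneGatedTTest(NamedTuple):
    levene_p: float
    t_statistic: float
    t_p: float
    variant: str  # "student" | "welch"


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least-squares fit of ``(log10_amount, ct)`` dilution points.

    Requires at least 3 points spanning more than one amount, and a
    negative slope (Ct must fall as template rises).
    """
    if len(points) < 3:
        raise StandardCurveError("need at least 3 dilution points")
    x = np.asarray([p[0] for p in points], float)
    y = np.asarray([p[1] for p in points], float)
    if np.ptp(x) == 0:
        raise StandardCurveError("zero variance in log10 amounts")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise StandardCurveError(
            f"non-negative slope {fit.slope:.3f}: Ct must decrease with amount"
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def quantify_sample(ct: float, curve: StandardCurve) -> float:
    """Template amount recovered from a Ct via the inverted standard curve."""
    if curve.slope >= 0:
        raise StandardCurveError("standard curve slope must be negative")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def relative_expression(target_amount: float, reference_amount: float) -> float:
    """Target amount normalised to the reference-gene amount."""
    if reference_amount <= 0:
        raise ZeroDivisionError("reference amount must be positive")
    return target_amount / reference_amount


def levene_gate_t_test(
    group_a: Sequence[float], group_b: Sequence[float], center: str = "mean"
) -> LeveneGatedTTest:
    """Two-sided t-test with the variant chosen by Levene's test.

    Classic mean-centred Levene by default (``center="median"`` gives the
    Brown–Forsythe variant); Student's pooled-variance t-test when
    levene_p > 0.05, Welch otherwise.  When both groups are internally
    constant the Levene statistic is undefined and equal variances are
    assumed (levene_p = 1); if the constant groups differ the separation is
    perfect and the p-value is reported as the smallest positive float with
    a warning.
    """
    if center not in ("mean", "median"):
        raise ValueError(f"center must be 'mean' or 'median', got {center!r}")
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise SampleSizeError("each group needs at least 2 observations")
    if a.std() == 0 and b.std() == 0:
        levene_p = 1.0
    else:
        levene_p = float(stats.levene(a, b, center=center)[1])
    variant = "student" if levene_p > 0.05 else "welch"
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return LeveneGatedTTest(levene_p, 0.0, 1.0, variant)
        warnings.warn(
            "zero within-group variance with distinct means: p reported as "
            "the smallest positive float",
            stacklevel=2,
        )
        return LeveneGatedTTest(levene_p, math.inf, float(np.finfo(float).tiny), variant)
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return LeveneGatedTTest(levene_p, float(t), float(p), variant)


def two_way_anova(samples: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Balanced fixed-effects side x day ANOVA.

    ``samples`` needs columns ``side`` (dorsal/ventral), ``day`` and the
    response ``value_col``; every side x day cell must hold the same number
    (>= 2) of replicates.  Returns a frame indexed by ``side``, ``day``,
    ``side:day`` and ``residual`` with sum-of-squares, df, F and p columns.
    Zero-variance effects are reported as F = 0, p = 1.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {"side", "day", value_col}
    if not required <= set(samples.columns):
        raise DesignError(f"samples need columns {sorted(required)}")
    cells = samples.groupby(["side", "day"], observed=True).size()
    if len(cells) != 4:
        raise DesignError("design must cover all four side x day cells")
    if cells.nunique() != 1 or cells.iloc[0] < 2:
        raise DesignError(
            "design must be balanced with >= 2 replicates per cell "
            f"(got {dict(cells)})"
        )
    data = samples.rename(columns={value_col: "_y"})
    model = smf.ols("_y ~ C(side) * C(day)", data=data).fit()
    with warnings.catch_warnings():
        # statsmodels warns on 0/0 F ratios; handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(side)": "side",
            "C(day)": "day",
            "C(side):C(day)": "side:day",
            "Residual": "residual",
        },
        columns={"sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p"},
    )
    eps = 1e-12 * max(1.0, float(np.abs(data["_y"]).max()) ** 2)
    resid_ss = float(table.loc["residual", "sum_sq"])
    for effect in ("side", "day", "side:day"):
        ss = float(table.loc[effect, "sum_sq"])
        if ss <= eps:
            table.loc[effect, ["F", "p"]] = (0.0, 1.0)
        elif resid_ss <= eps:
            table.loc[effect, ["F", "p"]] = (math.inf, 0.0)
    return table


def amounts_from_cts(
    samples: pd.DataFrame,
    curves: dict[str, StandardCurve],
) -> pd.DataFrame:
    """Back-transform each replicate Ct into an amount via its gene's curve.

    ``samples`` needs columns ``gene, side, day, replicate, ct``; the
    returned frame adds an ``amount`` column.
    """
    required = {"gene", "side", "day", "replicate", "ct"}
    if not required <= set(samples.columns):
        raise DesignError(f"samples need columns {sorted(required)}")
    missing = sorted(set(samples["gene"]) - set(curves))
    if missing:
        raise StandardCurveError(f"no standard curve for gene(s) {missing}")
    out = samples.copy()
    out["amount"] = [
        quantify_sample(ct, curves[gene])
        for gene, ct in zip(out["gene"], out["ct"])
    ]
    return out


def normalized_expression(
    amounts: pd.DataFrame, reference_gene: str
) -> pd.DataFrame:
    """Per-replicate amounts normalised to the mean reference-gene amount.

    The reference gene is averaged within each side x day condition (its
    replicates are not paired with the target's), then each target
    replicate amount is divided by that condition mean.  Rows for the
    reference gene itself are dropped.
    """
    if reference_gene not in set(amounts["gene"]):
        raise DesignError(f"reference gene {reference_gene!r} absent from samples")
    ref = (
        amounts[amounts["gene"] == reference_gene]
        .groupby(["side", "day"], observed=True)["amount"]
        .mean()
    )
    targets = amounts[amounts["gene"] != reference_gene].copy()
    ref_for_row = ref.loc[
        pd.MultiIndex.from_frame(targets[["side", "day"]])
    ].to_numpy()
    if (ref_for_row <= 0).any():
        raise ZeroDivisionError("reference amount must be positive in every cell")
    targets["relative_expression"] = targets["amount"] / ref_for_row
    return targets


class RatioEstimate(NamedTuple):
    ratio: float
    standard_error: float


def dorsoventral_ratio(
    amounts: pd.DataFrame, gene: str, day, reference_gene: str
) -> RatioEstimate:
    """Reference-normalised dorsal/ventral expression ratio with its SE.

    The estimator is (mean dorsal target / mean dorsal reference) over
    (mean ventral target / mean ventral reference) at the given day,
    computed from un-normalised amounts.  The delta-method SE propagates
    the sampling variance of all four group means — the reference gene's
    condition means divide whole groups, so their noise is invisible in
    normalised replicate spread and must be carried explicitly.
    """
    groups = []
    for g, side in ((gene, "dorsal"), (gene, "ventral"),
                    (reference_gene, "dorsal"), (reference_gene, "ventral")):
        sub = amounts[
            (amounts["gene"] == g) & (amounts["side"] == side) & (amounts["day"] == day)
        ]["amount"].to_numpy()
        if len(sub) < 2:
            raise SampleSizeError(f"need >= 2 replicates for {g}/{side}/day {day}")
        groups.append(sub)
    d_t, v_t, d_r, v_r = groups
    ratio = (d_t.mean() / d_r.mean()) / (v_t.mean() / v_r.mean())
    rel_var = sum(
        g.std(ddof=1) ** 2 / len(g) / g.mean() ** 2 for g in groups
    )
    return RatioEstimate(float(ratio), float(ratio * math.sqrt(rel_var)))
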