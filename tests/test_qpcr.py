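"""Standard-curve quantification and the validation statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from irisgradient import (
    SimulationSpec,
    StandardCurve,
    dorsoventral_ratio,
    fit_standard_curve,
    levene_gate_t_test,
    quantify_sample,
    relative_expression,
    simulate_qpcr,
    two_way_anova,
)
from irisgradient.errors import DesignError, SampleSizeError, StandardCurveError
from irisgradient.qpcr import (
    PERFECT_SLOPE,
    amounts_from_cts,
    normalized_expression,
)


class TestStandardCurve:
    def test_perfect_doubling_line(self):
        points = [(x, PERFECT_SLOPE * x + 30.0) for x in (-3, -2, -1, 0, 1)]
        curve = fit_standard_curve(points)
        assert curve.slope == pytest.approx(PERFECT_SLOPE, abs=1e-9)
        assert curve.intercept == pytest.approx(30.0, abs=1e-9)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_fits_rejected(self):
        with pytest.raises(StandardCurveError, match="3 dilution"):
            fit_standard_curve([(0, 30), (1, 27)])
        with pytest.raises(StandardCurveError, match="variance"):
            fit_standard_curve([(0, 30), (0, 27), (0, 25)])
        with pytest.raises(StandardCurveError, match="slope"):
            fit_standard_curve([(-1, 30), (0, 30), (1, 30)])  # flat line

    def test_noisy_slope_estimator_is_calibrated(self):
        """Slope errors over repeated noisy series behave like the OLS
        sampling theory says: centred, unit-scale z-scores, ~0 beyond 3."""
        x = np.repeat([-3.0, -2.0, -1.0, 0.0, 1.0], 3)
        se = 0.1 / math.sqrt(((x - x.mean()) ** 2).sum())
        z = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = PERFECT_SLOPE * x + 30.0 + rng.normal(0, 0.1, x.size)
            curve = fit_standard_curve(list(zip(x, y)))
            z.append((curve.slope - PERFECT_SLOPE) / se)
        z = np.asarray(z)
        assert abs(z.mean()) < 0.3
        assert 0.7 < z.std() < 1.4
        assert (np.abs(z) > 3).mean() <= 0.03

    @pytest.mark.parametrize(
        "ct_offset, expected_amount",
        [(0.0, 1.0), (PERFECT_SLOPE, 10.0), (-PERFECT_SLOPE, 0.1)],
    )
    def test_quantify_inverts_the_line(self, ct_offset, expected_amount):
        curve = StandardCurve(PERFECT_SLOPE, 30.0, 1.0)
        assert quantify_sample(30.0 + ct_offset, curve) == pytest.approx(
            expected_amount, rel=1e-9
        )

    def test_quantify_rejects_invalid_curve(self):
        with pytest.raises(StandardCurveError):
            quantify_sample(25.0, StandardCurve(0.5, 30.0, 1.0))

    def test_round_trip_on_dilution_series(self):
        curve = StandardCurve(-3.1, 28.0, 1.0)
        for amount in (1e-3, 1e-1, 1.0, 50.0):
            assert quantify_sample(
                curve.ct(math.log10(amount)), curve
            ) == pytest.approx(amount, rel=1e-9)


def test_relative_expression():
    assert relative_expression(2.0, 2.0) == 1.0
    assert relative_expression(4.0, 2.0) == 2.0
    with pytest.raises(ZeroDivisionError):
        relative_expression(1.0, 0.0)
    # scale invariance: units of the standard cancel
    assert relative_expression(4.0 * 7.3, 2.0 * 7.3) == pytest.approx(2.0)


class TestLeveneGatedTTest:
    def test_identical_groups(self):
        res = levene_gate_t_test([1, 2, 3], [1, 2, 3])
        assert res.levene_p == pytest.approx(1.0)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.t_p == pytest.approx(1.0)
        assert res.variant == "student"

    def test_unequal_variances_trigger_welch(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 10, 10)
        res = levene_gate_t_test(a, b)
        assert res.levene_p <= 0.05
        assert res.variant == "welch"

    def test_equal_variances_keep_student(self):
        rng = np.random.default_rng(13)
        res = levene_gate_t_test(rng.normal(0, 1, 10), rng.normal(1, 1, 10))
        assert res.levene_p > 0.05
        assert res.variant == "student"

    def test_degenerate_separation(self):
        with pytest.warns(UserWarning, match="zero within-group variance"):
            res = levene_gate_t_test([0, 0, 0], [5, 5, 5])
        assert res.t_p < 1e-300 and res.t_p > 0

    def test_sample_size_guard(self):
        with pytest.raises(SampleSizeError):
            levene_gate_t_test([1.0], [1.0, 2.0])

    def test_median_centering_option(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(0, 1, 12), rng.normal(0, 10, 12)
        mean_centred = levene_gate_t_test(a, b)
        median_centred = levene_gate_t_test(a, b, center="median")
        # both see the variance gap; the statistics differ by centring
        assert median_centred.variant == mean_centred.variant == "welch"
        assert median_centred.levene_p != mean_centred.levene_p
        with pytest.raises(ValueError):
            levene_gate_t_test(a, b, center="mode")


def _cells(dorsal4, ventral4, dorsal8, ventral8, n=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for side, day, mean in [
        ("dorsal", 4, dorsal4),
        ("ventral", 4, ventral4),
        ("dorsal", 8, dorsal8),
        ("ventral", 8, ventral8),
    ]:
        for _ in range(n):
            rows.append(
                {"side": side, "day": day, "value": mean + rng.normal(0, noise) if noise else mean}
            )
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_all_cells_identical(self):
        table = two_way_anova(_cells(2, 2, 2, 2))
        for effect in ("side", "day", "side:day"):
            assert table.loc[effect, "F"] == 0.0
            assert table.loc[effect, "p"] == 1.0

    def test_additive_effects_detected(self):
        # side +2, day +1, no interaction, sigma = 0.1
        table = two_way_anova(_cells(3, 1, 4, 2, noise=0.1, seed=21))
        assert table.loc["side", "p"] < 0.05
        assert table.loc["day", "p"] < 0.05
        assert table.loc["side:day", "p"] > table.loc["side", "p"]

    def test_pure_effect_with_zero_noise_is_infinite_f(self):
        table = two_way_anova(_cells(3, 1, 3, 1))
        assert math.isinf(table.loc["side", "F"]) and table.loc["side", "p"] == 0.0
        assert table.loc["day", "F"] == 0.0 and table.loc["day", "p"] == 1.0

    def test_design_guards(self):
        with pytest.raises(DesignError):
            two_way_anova(_cells(1, 2, 3, 4, n=1))
        unbalanced = pd.concat(
            [_cells(1, 2, 3, 4), _cells(1, 2, 3, 4).iloc[:1]], ignore_index=True
        )
        with pytest.raises(DesignError, match="balanced"):
            two_way_anova(unbalanced)
        with pytest.raises(DesignError, match="columns"):
            two_way_anova(pd.DataFrame({"side": [], "value": []}))


class TestSimulatedQpcrRecovery:
    def test_noise_free_run_recovers_true_levels_exactly(self):
        spec = SimulationSpec(seed=5, ct_noise_sd=0.0)
        standards, samples, truth = simulate_qpcr(spec)
        curves = {
            gene: fit_standard_curve(list(zip(sub["log10_amount"], sub["ct"])))
            for gene, sub in standards.groupby("gene")
        }
        normalized = normalized_expression(
            amounts_from_cts(samples, curves), spec.reference_gene
        )
        merged = normalized.merge(truth, on=["gene", "side", "day"])
        assert np.allclose(
            merged["relative_expression"], merged["true_amount"], rtol=1e-9
        )

    def test_planted_eightfold_gradient_recovered(self):
        spec = SimulationSpec(seed=6)
        standards, samples, _ = simulate_qpcr(spec)
        curves = {
            gene: fit_standard_curve(list(zip(sub["log10_amount"], sub["ct"])))
            for gene, sub in standards.groupby("gene")
        }
        amounts = amounts_from_cts(samples, curves)
        estimate = dorsoventral_ratio(amounts, "TBX5", 4, spec.reference_gene)
        assert abs(estimate.ratio - 8.0) < 2 * estimate.standard_error
        normalized = normalized_expression(amounts, spec.reference_gene)
        tbx5 = normalized[normalized["gene"] == "TBX5"]
        anova = two_way_anova(tbx5, value_col="relative_expression")
        assert anova.loc["side", "p"] < 0.05

    def test_ratio_se_reflects_reference_noise(self):
        # noise only in the reference gene must still widen the SE
        spec = SimulationSpec(seed=44, ct_noise_sd=0.0)
        standards, samples, _ = simulate_qpcr(spec)
        rng = np.random.default_rng(9)
        ref_rows = samples["gene"] == spec.reference_gene
        samples.loc[ref_rows, "ct"] += rng.normal(0, 0.3, ref_rows.sum())
        curves = {
            gene: fit_standard_curve(list(zip(sub["log10_amount"], sub["ct"])))
            for gene, sub in standards.groupby("gene")
        }
        amounts = amounts_from_cts(samples, curves)
        estimate = dorsoventral_ratio(amounts, "TBX5", 4, spec.reference_gene)
        assert estimate.standard_error > 0
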