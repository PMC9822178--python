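"""Epidemiological layer: odds ratios, chi-square, shares, temporal
contrasts, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from sentifuse.epi import (
    Chi2Result,
    PowerSpec,
    TwoByTwo,
    chisq_power,
    chisq_power_sample_size,
    format_ratio,
    odds_ratio,
    percent_change,
    sentiment_share_table,
    temporal_negative_analysis,
    two_proportion_chisq,
)
from sentifuse.errors import InputError, ZeroCellError
from sentifuse.synthetic import SimulationConfig, simulate_frame

cells = st.integers(min_value=1, max_value=5000)


class TestOddsRatio:
    def test_null_table(self):
        r = odds_ratio(TwoByTwo(1, 1, 1, 1))
        assert r.or_point == pytest.approx(1.0)
        assert r.z == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_two_period_negative_contrast_counts(self):
        """Peri/pre negative-vs-rest table from two-period study counts of
        roughly 3e5 posts: OR ~1.398, Wald CI ~(1.378, 1.418)."""
        r = odds_ratio(TwoByTwo(91242, 74518, 65164, 74397))
        assert r.or_point == pytest.approx(1.3979, abs=5e-4)
        assert r.ci_low == pytest.approx(1.378, abs=1e-3)
        assert r.ci_high == pytest.approx(1.418, abs=1e-3)
        assert format_ratio(r.or_point, "truncate") == 1.39

    def test_row_scaling_invariance(self):
        base = odds_ratio(TwoByTwo(12, 34, 56, 78)).or_point
        scaled = odds_ratio(TwoByTwo(120, 340, 56, 78)).or_point
        assert scaled == pytest.approx(base)

    def test_zero_cell_raises_unless_haldane(self):
        with pytest.raises(ZeroCellError):
            odds_ratio(TwoByTwo(0, 5, 5, 5))
        r = odds_ratio(TwoByTwo(0, 5, 5, 5), haldane=True)
        assert r.or_point > 0

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_reciprocal_identity(self, a, b, c, d):
        r1 = odds_ratio(TwoByTwo(a, b, c, d))
        r2 = odds_ratio(TwoByTwo(c, d, a, b))
        assert r1.or_point == pytest.approx(1 / r2.or_point)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ci_brackets_point_and_shrinks(self, a, b, c, d):
        r = odds_ratio(TwoByTwo(a, b, c, d))
        assert r.ci_low <= r.or_point <= r.ci_high
        big = odds_ratio(TwoByTwo(10 * a, 10 * b, 10 * c, 10 * d))
        assert (big.ci_high - big.ci_low) < (r.ci_high - r.ci_low) + 1e-12


class TestChiSquare:
    def test_null_table(self):
        r = two_proportion_chisq(TwoByTwo(1, 1, 1, 1))
        assert r.chi2 == 0 and r.p == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        assert two_proportion_chisq(TwoByTwo(30, 70, 10, 90)).chi2 == pytest.approx(12.5)

    def test_matches_scipy_contingency(self):
        t = TwoByTwo(30, 70, 10, 90)
        expected = stats.chi2_contingency(
            [[30, 70], [10, 90]], correction=False
        )
        r = two_proportion_chisq(t)
        assert r.chi2 == pytest.approx(expected.statistic)
        assert r.p == pytest.approx(expected.pvalue)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_chi2_equals_z_squared(self, a, b, c, d):
        r = two_proportion_chisq(TwoByTwo(a, b, c, d))
        assert r.z**2 == pytest.approx(r.chi2, rel=1e-9)

    def test_empty_margin_rejected(self):
        with pytest.raises(InputError):
            two_proportion_chisq(TwoByTwo(0, 0, 5, 5))


class TestPercentChange:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(100, 150, 50.0), (139561, 165760, pytest.approx(18.772, abs=1e-3)), (100, 100, 0.0)],
    )
    def test_examples(self, before, after, expected):
        assert percent_change(before, after) == expected

    def test_zero_before_rejected(self):
        with pytest.raises(InputError):
            percent_change(0, 10)


class TestShareTable:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["label", "period"])

    def test_hand_tally(self):
        rows = (
            [("negative", "peripandemic")] * 6
            + [("positive", "peripandemic")] * 2
            + [("negative", "prepandemic")] * 1
            + [("neutral", "prepandemic")] * 1
        )
        table = sentiment_share_table(self._frame(rows))
        assert table.loc["negative", "n_peri"] == 6
        assert table.loc["negative", "pct_peri"] == 75.0
        assert table.loc["total", "n_total"] == 10

    def test_single_sentiment_is_total(self):
        rows = [("negative", "prepandemic")] * 3 + [("negative", "peripandemic")] * 3
        table = sentiment_share_table(self._frame(rows))
        assert table.loc["negative", "pct_pre"] == 100.0
        assert table.loc["positive", "n_total"] == 0

    def test_out_of_window_counted(self):
        rows = [("negative", "prepandemic"), ("negative", "peripandemic"),
                ("negative", "out_of_window")]
        table = sentiment_share_table(self._frame(rows))
        assert table.attrs["n_out_of_window"] == 1
        assert table.loc["total", "n_total"] == 2


class TestTemporal:
    def test_null_design_gives_unit_ors(self, rng):
        cfg = SimulationConfig(
            n_pre=6000, n_peri=6000,
            after_midnight_negative_odds_multiplier=1.0, seed=2,
        )
        report = temporal_negative_analysis(simulate_frame(cfg))
        r = report.contrasts["after_vs_before"]
        assert r.ci_low < 1.0 < r.ci_high
        assert np.isclose(r.or_point, 1.0, atol=0.15)

    def test_multiplier_recovery(self):
        """A corpus generated with after-midnight negative odds x1.5 yields
        an overall after-vs-before OR near 1.5 (equal-period prevalences, so
        the pooled contrast is the generating parameter)."""
        prev = (0.5, 0.28, 0.22)
        cfg = SimulationConfig(
            n_pre=10_000, n_peri=10_000,
            prevalence_pre=prev, prevalence_peri=prev,
            after_midnight_negative_odds_multiplier=1.5, seed=12,
        )
        report = temporal_negative_analysis(simulate_frame(cfg))
        r = report.contrasts["after_vs_before"]
        assert 1.4 < r.or_point < 1.6
        assert r.ci_low < 1.5 < r.ci_high

    def test_hourly_distribution_conserves_negative_count(self):
        cfg = SimulationConfig(n_pre=3000, n_peri=3000, seed=4)
        frame = simulate_frame(cfg)
        report = temporal_negative_analysis(frame)
        assert report.hourly_negative.sum() == (frame["label"] == "negative").sum()

    def test_zero_cell_names_contrast(self):
        frame = pd.DataFrame(
            {
                "label": ["negative", "negative"],
                "period": ["prepandemic", "peripandemic"],
                "bucket": ["after_midnight", "after_midnight"],
                "hour": [2, 3],
            }
        )
        with pytest.raises(ZeroCellError, match="after_vs_before"):
            temporal_negative_analysis(frame)


class TestPower:
    def test_study_design_needs_143(self):
        assert chisq_power_sample_size(PowerSpec(0.3, 0.05, 0.80, 5)) == 143

    def test_df1_medium_effect_needs_32(self):
        assert chisq_power_sample_size(PowerSpec(0.5, 0.05, 0.80, 1)) == 32

    def test_returned_n_is_minimal(self):
        for spec in (PowerSpec(0.3, 0.05, 0.80, 5), PowerSpec(0.5, 0.05, 0.80, 1),
                     PowerSpec(0.1, 0.01, 0.9, 2)):
            n = chisq_power_sample_size(spec)
            assert chisq_power(spec, n) >= spec.power
            assert chisq_power(spec, n - 1) < spec.power

    def test_monotone_in_effect_size(self):
        small = chisq_power_sample_size(PowerSpec(0.3, 0.05, 0.80, 5))
        large = chisq_power_sample_size(PowerSpec(0.6, 0.05, 0.80, 5))
        assert large < small

    def test_power_monotone_in_n(self):
        spec = PowerSpec(0.3, 0.05, 0.80, 5)
        powers = [chisq_power(spec, n) for n in (50, 100, 143, 200)]
        assert powers == sorted(powers)

    def test_invalid_specs_rejected(self):
        with pytest.raises(InputError):
            PowerSpec(0.0, 0.05, 0.8, 1)
        with pytest.raises(InputError):
            PowerSpec(0.3, 1.5, 0.8, 1)


class TestDisplay:
    @pytest.mark.parametrize(
        "x,mode,expected",
        [
            (1.3979, "truncate", 1.39),
            (1.3979, "round", 1.40),
            (0.6058, "truncate", 0.60),
            (0.6166, "truncate", 0.61),
            (0.9902, "round", 0.99),
            (0.9902, "truncate", 0.99),
        ],
    )
    def test_ratio_modes(self, x, mode, expected):
        assert format_ratio(x, mode) == expected
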