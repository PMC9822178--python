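"""Epidemiological statistics for two-period sentiment surveillance.

The analysis layer works on 2x2 exposure-by-outcome tables

    a = exposed with outcome      b = exposed without
    c = unexposed with outcome    d = unexposed without

with exposure typically "peripandemic year" or "after-midnight post" and
outcome "negative sentiment". It provides:

* odds ratios OR = ad/bc with Wald 95% intervals
  exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)), z = ln OR / SE and a
  two-sided normal p-value — the same estimate a univariate logistic
  regression of outcome on exposure would report, in closed form;
* Pearson chi-square on the 2x2 without continuity correction, with the
  signed two-proportion z (z^2 = chi^2);
* per-period sentiment share tables with peri-vs-pre contrasts per class;
* the before/after-midnight temporal analysis;
* minimal sample size for a chi-square test of effect size w (noncentral
  chi-square power, lambda = n * w^2).

Published tables in this literature often *truncate* rather than round
ratios to two decimals; :func:`format_ratio` supports both display modes
(default ``round``; use ``truncate`` to match such tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor, isnan, sqrt
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import LABEL_ORDER, ClockBucket, StudyPeriod
from .errors import InputError, ZeroCellError
from .evaluation import format_pct

__all__ = [
    "TwoByTwo",
    "ORResult",
    "Chi2Result",
    "PowerSpec",
    "TemporalReport",
    "odds_ratio",
    "two_proportion_chisq",
    "percent_change",
    "sentiment_share_table",
    "temporal_negative_analysis",
    "chisq_power",
    "chisq_power_sample_size",
    "format_ratio",
]

_Z95 = 1.959963984540054  # standard normal 97.5th percentile


@dataclass(frozen=True)
class TwoByTwo:
    """Counts a, b, c, d: exposed/unexposed (rows) by outcome/no-outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InputError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ORResult:
    or_point: float
    ci_low: float
    ci_high: float
    z: float
    p: float


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    z: float
    p: float


def odds_ratio(t: TwoByTwo, haldane: bool = False) -> ORResult:
    """Odds ratio with Wald 95% CI, z-statistic and two-sided p.

    A zero cell makes the estimate or its interval undefined and raises
    :class:`~sentifuse.errors.ZeroCellError`; pass ``haldane=True`` for an
    explicit Haldane-Anscombe 0.5 correction instead (never applied
    silently).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif 0 in (a, b, c, d):
        raise ZeroCellError(
            f"zero cell in 2x2 table {(t.a, t.b, t.c, t.d)}; "
            "odds ratio undefined (haldane=True applies a 0.5 correction)"
        )
    point = (a * d) / (b * c)
    se = sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(point)
    z = log_or / se
    p = 2 * stats.norm.sf(abs(z))
    return ORResult(
        or_point=float(point),
        ci_low=float(np.exp(log_or - _Z95 * se)),
        ci_high=float(np.exp(log_or + _Z95 * se)),
        z=float(z),
        p=float(p),
    )


def two_proportion_chisq(t: TwoByTwo) -> Chi2Result:
    """Pearson chi-square on the 2x2 (df=1, no continuity correction).

    Equivalent to the pooled two-proportion z-test: z = sign(ad - bc) *
    sqrt(chi2), p two-sided from chi-square with 1 df.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise InputError(f"empty margin in 2x2 table {(a, b, c, d)}")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    z = float(np.sign(a * d - b * c) * sqrt(chi2))
    return Chi2Result(float(chi2), z, float(stats.chi2.sf(chi2, df=1)))


def percent_change(n_before: int, n_after: int) -> float:
    """Signed percent change 100 * (after - before) / before."""
    if n_before <= 0:
        raise InputError("n_before must be positive")
    return 100.0 * (n_after - n_before) / n_before


def _require_columns(frame: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise InputError(f"analysis frame missing column(s): {missing}")


def _in_window(frame: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    keep = frame["period"].isin(
        [StudyPeriod.PREPANDEMIC.value, StudyPeriod.PERIPANDEMIC.value]
    )
    return frame.loc[keep], int((~keep).sum())


def sentiment_share_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-period sentiment counts, within-period percentages, and the
    peri-vs-pre contrast (chi-square p, z, OR with Wald CI) per class.

    ``frame`` needs columns ``label`` and ``period``; out-of-window records
    are dropped and counted in the result's ``attrs['n_out_of_window']``.
    One row per sentiment class plus a ``total`` row.
    """
    _require_columns(frame, ("label", "period"))
    frame, n_out = _in_window(frame)
    if frame.empty:
        raise InputError("no in-window records to tabulate")
    pre = frame["period"] == StudyPeriod.PREPANDEMIC.value
    n_pre = int(pre.sum())
    n_peri = int(len(frame) - n_pre)
    n_total = len(frame)
    rows = []
    for lab in LABEL_ORDER:
        is_lab = frame["label"] == lab.value
        k_pre = int((is_lab & pre).sum())
        k_peri = int((is_lab & ~pre).sum())
        k_tot = k_pre + k_peri
        table = TwoByTwo(k_peri, n_peri - k_peri, k_pre, n_pre - k_pre)
        try:
            orr = odds_ratio(table)
            chi = two_proportion_chisq(table)
            contrast = dict(
                p=chi.p, z=abs(chi.z), odds_ratio=orr.or_point,
                ci_low=orr.ci_low, ci_high=orr.ci_high,
            )
        except (ZeroCellError, InputError):
            contrast = dict(p=np.nan, z=np.nan, odds_ratio=np.nan,
                            ci_low=np.nan, ci_high=np.nan)
        rows.append(
            {
                "sentiment": lab.value,
                "n_total": k_tot,
                "pct_total": format_pct(k_tot / n_total),
                "n_pre": k_pre,
                "pct_pre": format_pct(k_pre / n_pre) if n_pre else np.nan,
                "n_peri": k_peri,
                "pct_peri": format_pct(k_peri / n_peri) if n_peri else np.nan,
                **contrast,
            }
        )
    rows.append(
        {
            "sentiment": "total",
            "n_total": n_total,
            "pct_total": 100.0,
            "n_pre": n_pre,
            "pct_pre": 100.0,
            "n_peri": n_peri,
            "pct_peri": 100.0,
            "p": np.nan, "z": np.nan, "odds_ratio": np.nan,
            "ci_low": np.nan, "ci_high": np.nan,
        }
    )
    out = pd.DataFrame(rows).set_index("sentiment")
    out.attrs["n_out_of_window"] = n_out
    return out


@dataclass
class TemporalReport:
    """Before/after-midnight analysis of negative sentiment.

    contrasts: named 2x2 odds ratios —
      ``after_vs_before``            negative vs non-negative, both periods pooled
      ``peri_vs_pre_before``         within the before-midnight bucket
      ``peri_vs_pre_after``          within the after-midnight bucket
      ``after_vs_before_pre``        within the prepandemic year
      ``after_vs_before_peri``       within the peripandemic year
    hourly_negative: negative-post counts per local hour 0-23.
    pct_negative_by_bucket: % of posts in each bucket that are negative.
    pct_negative_after_midnight: share of all negative posts that fall after
    midnight, as a percentage.
    """

    contrasts: Mapping[str, ORResult]
    hourly_negative: np.ndarray
    pct_negative_by_bucket: Mapping[str, float]
    pct_negative_after_midnight: float
    n_out_of_window: int = 0


def _neg_table(frame: pd.DataFrame, exposed: pd.Series) -> TwoByTwo:
    neg = frame["label"] == "negative"
    return TwoByTwo(
        int((exposed & neg).sum()),
        int((exposed & ~neg).sum()),
        int((~exposed & neg).sum()),
        int((~exposed & ~neg).sum()),
    )


def temporal_negative_analysis(frame: pd.DataFrame) -> TemporalReport:
    """Build the before/after-midnight contrasts on negative sentiment.

    ``frame`` needs columns label, period, bucket and (for the hourly
    distribution) hour. Any zero cell propagates as
    :class:`~sentifuse.errors.ZeroCellError` naming the contrast.
    """
    _require_columns(frame, ("label", "period", "bucket"))
    frame, n_out = _in_window(frame)
    if frame.empty:
        raise InputError("no in-window records to analyse")
    after = frame["bucket"] == ClockBucket.AFTER_MIDNIGHT.value
    peri = frame["period"] == StudyPeriod.PERIPANDEMIC.value
    neg = frame["label"] == "negative"

    slices = {
        "after_vs_before": (frame, after),
        "peri_vs_pre_before": (frame.loc[~after], peri.loc[~after]),
        "peri_vs_pre_after": (frame.loc[after], peri.loc[after]),
        "after_vs_before_pre": (frame.loc[~peri], after.loc[~peri]),
        "after_vs_before_peri": (frame.loc[peri], after.loc[peri]),
    }
    contrasts: dict[str, ORResult] = {}
    for name, (sub, exposed) in slices.items():
        try:
            contrasts[name] = odds_ratio(_neg_table(sub, exposed))
        except ZeroCellError as exc:
            raise ZeroCellError(f"contrast {name!r}: {exc}") from None

    if "hour" in frame.columns:
        hourly = (
            frame.loc[neg, "hour"]
            .value_counts()
            .reindex(range(24), fill_value=0)
            .sort_index()
            .to_numpy()
        )
    else:
        hourly = np.zeros(24, dtype=int)
    n_neg = int(neg.sum())
    pct_bucket = {
        ClockBucket.AFTER_MIDNIGHT.value: format_pct(
            float((neg & after).sum() / after.sum()) if after.any() else np.nan
        ),
        ClockBucket.BEFORE_MIDNIGHT.value: format_pct(
            float((neg & ~after).sum() / (~after).sum()) if (~after).any() else np.nan
        ),
    }
    pct_after = format_pct(float((neg & after).sum() / n_neg)) if n_neg else np.nan
    return TemporalReport(contrasts, hourly, pct_bucket, pct_after, n_out)


@dataclass(frozen=True)
class PowerSpec:
    """Chi-square power design: Cohen effect size w, level alpha, target
    power, degrees of freedom."""

    effect_size_w: float
    alpha: float = 0.05
    power: float = 0.80
    df: int = 1

    def __post_init__(self):
        if self.effect_size_w <= 0:
            raise InputError("effect size w must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise InputError("alpha and power must lie in (0, 1)")
        if self.df < 1:
            raise InputError("df must be >= 1")


def chisq_power(spec: PowerSpec, n: int) -> float:
    """Power of the chi-square test at sample size n: the noncentral
    chi-square (lambda = n w^2) mass above the central critical value."""
    crit = stats.chi2.ppf(1.0 - spec.alpha, spec.df)
    return float(stats.ncx2.sf(crit, spec.df, n * spec.effect_size_w**2))


def chisq_power_sample_size(spec: PowerSpec, n_max: int = 10_000_000) -> int:
    """Smallest integer n whose chi-square power reaches the target.

    Bisection over [1, n_max] on the monotone power function; the returned n
    satisfies power(n-1) < target <= power(n).
    """
    if chisq_power(spec, n_max) < spec.power:
        raise InputError(f"target power unattainable within n <= {n_max}")
    lo, hi = 0, n_max  # power(lo) < target <= power(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if chisq_power(spec, mid) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi


def format_ratio(x: float, mode: str = "round", decimals: int = 2) -> float:
    """Display a ratio to ``decimals`` places, either rounded (half away
    from zero) or truncated toward zero, as published tables variously do."""
    if isnan(x):
        return x
    scale = 10**decimals
    if mode == "truncate":
        return floor(abs(x) * scale) / scale * (1 if x >= 0 else -1)
    if mode == "round":
        return format_pct(x / 100, decimals=decimals)
    raise InputError(f"unknown display mode {mode!r}")
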