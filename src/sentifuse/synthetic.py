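"""Seeded generators for two-period tweet corpora and noisy classifier
ensembles.

The generator emulates the statistical structure the surveillance analysis
assumes: a prepandemic (2019) and a peripandemic (2020) record stream with
per-period sentiment prevalences, an hour-of-day posting profile, and an
elevated after-midnight negativity expressed as an odds multiplier. The
multiplier is injected as a logistic tilt on the negative-class odds for
after-midnight hours, and the per-bucket baseline odds are calibrated (by
root finding) so that

* the marginal per-period negative share equals the configured prevalence
  exactly in expectation, and
* the population odds ratio of the after-vs-before-midnight negative
  contrast equals the configured multiplier exactly,

making the generating parameters the estimands of the downstream analysis.
Non-negative mass is split between neutral and positive in the configured
ratio, so those marginal prevalences are preserved too.

Texts are assembled from a small sentiment-keyed template lexicon, always
contain the study keyword ("insomnia"), and are salted with URLs, hashtags,
mentions and emoji so the cleaning stage is exercised end to end. All
randomness flows from one integer seed through numpy's PCG64 generator,
which is platform-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .backends import MockParams, mock_classify_batch
from .corpus import (
    LABEL_ORDER,
    ClockBucket,
    Corpus,
    SentimentLabel,
    StudyPeriod,
    TweetRecord,
)
from .errors import InputError

__all__ = [
    "SimulationConfig",
    "default_study_profile",
    "simulate_frame",
    "simulate_corpus",
    "simulate_ensemble_outputs",
]

#: local hours belonging to the after-midnight bucket (midnight through noon)
_AFTER_HOURS = np.arange(24) <= 12

_PERIOD_START = {
    StudyPeriod.PREPANDEMIC: datetime(2019, 1, 1, tzinfo=timezone.utc),
    StudyPeriod.PERIPANDEMIC: datetime(2020, 1, 1, tzinfo=timezone.utc),
}
_PERIOD_DAYS = {StudyPeriod.PREPANDEMIC: 365, StudyPeriod.PERIPANDEMIC: 366}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the corpus generator.

    prevalences are (negative, neutral, positive) triples and are *marginal*
    per-period shares; the after-midnight multiplier acts on negative odds
    within the after-midnight hours while those marginals are held fixed.
    """

    n_pre: int = 13_956
    n_peri: int = 16_576
    prevalence_pre: tuple = (0.467, 0.285, 0.248)
    prevalence_peri: tuple = (0.550, 0.283, 0.167)
    after_midnight_negative_odds_multiplier: float = 1.43
    hour_weights: tuple = tuple([1.0] * 24)
    classifiers: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        for name, prev in (
            ("prevalence_pre", self.prevalence_pre),
            ("prevalence_peri", self.prevalence_peri),
        ):
            p = np.asarray(prev, dtype=float)
            if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise InputError(f"{name} must be a probability triple summing to 1")
        if self.n_pre < 0 or self.n_peri < 0:
            raise InputError("sample sizes must be non-negative")
        if self.after_midnight_negative_odds_multiplier <= 0:
            raise InputError("odds multiplier must be positive")
        w = np.asarray(self.hour_weights, dtype=float)
        if w.shape != (24,) or np.any(w < 0) or w.sum() <= 0:
            raise InputError("hour_weights must be 24 non-negative weights, not all zero")


def default_study_profile(seed: int = 0) -> SimulationConfig:
    """Study conditions at one-tenth scale: per-period sizes 13,956 and
    16,576; marginal prevalences (0.467, 0.285, 0.248) prepandemic and
    (0.550, 0.283, 0.167) peripandemic; after-midnight negative-odds
    multiplier 1.43; five symmetric-confusion mock classifiers with
    accuracies 0.803, 0.527, 0.530, 0.493 and 0.453."""
    accuracies = (0.803, 0.527, 0.530, 0.493, 0.453)
    classifiers = tuple(
        MockParams.symmetric(a, concentration=20.0, seed=seed + i)
        for i, a in enumerate(accuracies)
    )
    return SimulationConfig(classifiers=classifiers, seed=seed)


def _base_log_odds(p_marginal: float, multiplier: float, f_after: float) -> float:
    """Before-midnight negative log-odds such that the hour-mixture marginal
    negative share equals ``p_marginal`` when after-midnight odds are
    ``multiplier`` times larger."""
    if not 0 < p_marginal < 1:
        raise InputError("negative prevalence must lie strictly in (0, 1)")
    if multiplier == 1.0:
        return float(np.log(p_marginal / (1 - p_marginal)))

    def gap(lo: float) -> float:
        o = np.exp(lo)
        p_after = multiplier * o / (1 + multiplier * o)
        p_before = o / (1 + o)
        return f_after * p_after + (1 - f_after) * p_before - p_marginal

    return float(brentq(gap, -40.0, 40.0, xtol=1e-13))


def _draw_labels(
    after: np.ndarray,
    prevalence: Sequence[float],
    multiplier: float,
    f_after: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Label index per record (0 neg, 1 neu, 2 pos) given bucket membership."""
    p_neg, p_neu, p_pos = (float(x) for x in prevalence)
    lo = _base_log_odds(p_neg, multiplier, f_after)
    odds = np.where(after, multiplier * np.exp(lo), np.exp(lo))
    p_neg_given = odds / (1 + odds)
    n = after.shape[0]
    u1 = rng.random(n)
    u2 = rng.random(n)
    q_neu = p_neu / (p_neu + p_pos) if (p_neu + p_pos) > 0 else 1.0
    labels = np.where(u1 < p_neg_given, 0, np.where(u2 < q_neu, 1, 2))
    return labels


def _simulate_period(
    period: StudyPeriod,
    n: int,
    prevalence: Sequence[float],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    w = np.asarray(cfg.hour_weights, dtype=float)
    w = w / w.sum()
    f_after = float(w[_AFTER_HOURS].sum())
    hours = rng.choice(24, size=n, p=w)
    after = _AFTER_HOURS[hours]
    labels = _draw_labels(
        after, prevalence, cfg.after_midnight_negative_odds_multiplier, f_after, rng
    )
    days = rng.integers(0, _PERIOD_DAYS[period], size=n)
    minutes = rng.integers(0, 60, size=n)
    seconds = rng.integers(0, 60, size=n)
    start = np.datetime64(_PERIOD_START[period].replace(tzinfo=None))
    ts = (
        start
        + days.astype("timedelta64[D]")
        + hours.astype("timedelta64[h]")
        + minutes.astype("timedelta64[m]")
        + seconds.astype("timedelta64[s]")
    )
    prefix = "pre" if period is StudyPeriod.PREPANDEMIC else "peri"
    return pd.DataFrame(
        {
            "id": [f"{prefix}-{i:06d}" for i in range(n)],
            "label": [LABEL_ORDER[k].value for k in labels],
            "timestamp": ts,
            "period": period.value,
            "bucket": np.where(
                after,
                ClockBucket.AFTER_MIDNIGHT.value,
                ClockBucket.BEFORE_MIDNIGHT.value,
            ),
            "hour": hours,
        }
    )


def simulate_frame(cfg: SimulationConfig) -> pd.DataFrame:
    """Vectorised core of the generator: one row per record with columns
    id, label, timestamp (numpy UTC), period, bucket, hour. This frame is
    the direct input of the statistics layer; :func:`simulate_corpus` wraps
    it with generated texts."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    parts = []
    if cfg.n_pre:
        parts.append(
            _simulate_period(
                StudyPeriod.PREPANDEMIC, cfg.n_pre, cfg.prevalence_pre, cfg, rng
            )
        )
    if cfg.n_peri:
        parts.append(
            _simulate_period(
                StudyPeriod.PERIPANDEMIC, cfg.n_peri, cfg.prevalence_peri, cfg, rng
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=["id", "label", "timestamp", "period", "bucket", "hour"]
        )
    return pd.concat(parts, ignore_index=True)


# --- text templating -------------------------------------------------------

_OPENINGS = {
    "negative": [
        "Another awful night with",
        "So exhausted and miserable, this",
        "I hate how bad my",
        "Crying at 3am again, the",
        "Completely drained, worst",
    ],
    "neutral": [
        "Reading an article about",
        "Someone asked me about",
        "New podcast episode on",
        "Survey results about",
        "A thread discussing",
    ],
    "positive": [
        "Finally beating my",
        "Great tips that cured my",
        "So grateful my battle with",
        "Feeling hopeful about my",
        "Good news about treating",
    ],
}
_TAILS = {
    "negative": [
        "insomnia is ruining everything",
        "insomnia keeps me awake all night",
        "insomnia makes work unbearable",
        "insomnia and I feel terrible",
    ],
    "neutral": [
        "insomnia statistics this year",
        "insomnia and sleep hygiene",
        "insomnia in adults worldwide",
        "insomnia research findings",
    ],
    "positive": [
        "insomnia with better sleep habits",
        "insomnia thanks to a new routine",
        "insomnia is finally over",
        "insomnia and sleeping well now",
    ],
}
_SALTS = [
    "",
    " https://t.co/{h}",
    " #insomnia #sleep",
    " @sleepdoc",
    " \U0001f62b",
    " RT_chain https://t.co/{h} \U0001f634",
]


def _make_texts(labels: Sequence[str], rng: np.random.Generator) -> list[str]:
    n = len(labels)
    oi = rng.integers(0, 5, size=n)
    ti = rng.integers(0, 4, size=n)
    si = rng.integers(0, len(_SALTS), size=n)
    hashes = rng.integers(0, 36**6, size=n)
    texts = []
    for k in range(n):
        lab = labels[k]
        salt = _SALTS[si[k]].format(h=np.base_repr(hashes[k], 36).lower())
        texts.append(f"{_OPENINGS[lab][oi[k]]} {_TAILS[lab][ti[k]]}{salt}")
    return texts


def simulate_corpus(cfg: SimulationConfig, with_text: bool = True) -> Corpus:
    """Generate a gold-labelled corpus under the configured study conditions.

    Fully reproducible under the config seed (same seed, byte-identical
    output). ``with_text=False`` skips text assembly for purely statistical
    experiments where only labels and timestamps matter.
    """
    frame = simulate_frame(cfg)
    rng = np.random.default_rng(cfg.seed + 1_000_000)  # separate text stream
    texts = (
        _make_texts(frame["label"].tolist(), rng)
        if with_text and len(frame)
        else [""] * len(frame)
    )
    records = []
    for row, text in zip(frame.itertuples(index=False), texts):
        ts = pd.Timestamp(row.timestamp).to_pydatetime().replace(tzinfo=timezone.utc)
        records.append(
            TweetRecord(
                id=row.id,
                text=text or f"placeholder insomnia {row.id}",
                timestamp=ts,
                lang="en",
                gold_label=SentimentLabel(row.label),
                period=StudyPeriod(row.period),
                bucket=ClockBucket(row.bucket),
            )
        )
    return Corpus(records, provenance=f"simulated(seed={cfg.seed})")


def simulate_ensemble_outputs(
    corpus: Corpus,
    classifiers: Sequence[MockParams],
    seed: Optional[int] = None,
    names: Optional[Sequence[str]] = None,
) -> dict[str, pd.DataFrame]:
    """Mock-classify every record with every classifier.

    Outputs are conditionally independent across models given the gold
    labels. Returns model name -> DataFrame indexed by record id with
    columns p_negative, p_neutral, p_positive — the interchange shape the
    fusion layer consumes.
    """
    if not list(classifiers):
        raise InputError("need at least one classifier")
    golds = []
    ids = []
    for r in corpus:
        if r.gold_label is None:
            raise InputError(f"record {r.id} lacks a gold label")
        golds.append(r.gold_label)
        ids.append(r.id)
    names = list(names) if names else [f"model{i+1}" for i in range(len(classifiers))]
    if len(names) != len(classifiers):
        raise InputError("names must match the number of classifiers")
    out: dict[str, pd.DataFrame] = {}
    for i, (name, params) in enumerate(zip(names, classifiers)):
        stream_seed = params.seed if seed is None else (seed * 1009 + i) % (2**31 - 1)
        rng = np.random.default_rng(stream_seed)
        probs = mock_classify_batch(golds, params, rng)
        out[name] = pd.DataFrame(
            probs, index=pd.Index(ids, name="id"),
            columns=["p_negative", "p_neutral", "p_positive"],
        )
    return out
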