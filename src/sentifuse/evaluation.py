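"""Classifier scoring: confusion matrices, one-vs-rest class metrics,
Cohen's kappa, and ensemble-subset sweeps over DST fusion.

Per-class metrics follow the one-vs-rest reduction of the 3x3 gold-vs-
predicted confusion matrix: for class c, TP is the diagonal cell, FN the
rest of its row, FP the rest of its column and TN everything else. Then

    sensitivity = TP / (TP + FN)        precision = TP / (TP + FP)
    accuracy    = (TP + TN) / total     F1 = 2PR / (P + R)

Ratios with zero denominators are *flagged undefined* (NaN plus a flag),
never coerced to 0. Displayed percentages round half-away-from-zero to one
decimal; raw proportions are preserved in machine output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from math import isnan, nan
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score
from sklearn.metrics import confusion_matrix as _sk_confusion

from .backends import validate_probs
from .corpus import LABEL_ORDER, SentimentLabel
from .dst import bba_from_probs, combine_all, decide
from .errors import InputError, TotalConflictError

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion_matrix",
    "class_metrics",
    "overall_accuracy",
    "cohen_kappa",
    "fuse_records",
    "sweep_combinations",
    "format_pct",
]

_LABEL_VALUES = [lab.value for lab in LABEL_ORDER]

ConfusionMatrix = np.ndarray  # 3x3 counts, rows = gold, columns = predicted


def _as_values(labels: Iterable) -> list[str]:
    return [SentimentLabel(lab).value for lab in labels]


def confusion_matrix(gold: Sequence, predicted: Sequence) -> ConfusionMatrix:
    """3x3 gold-vs-predicted counts in canonical label order."""
    gold = _as_values(gold)
    predicted = _as_values(predicted)
    if len(gold) != len(predicted) or not gold:
        raise InputError("gold and predicted must have equal nonzero length")
    return _sk_confusion(gold, predicted, labels=_LABEL_VALUES)


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single class; NaN fields are listed in
    ``undefined`` with the reason being a zero denominator."""

    sensitivity: float
    precision: float
    accuracy: float
    f1: float
    undefined: frozenset = field(default_factory=frozenset)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else nan


def class_metrics(cm: ConfusionMatrix, cls: SentimentLabel) -> ClassMetrics:
    cm = np.asarray(cm)
    if cm.shape != (3, 3) or np.any(cm < 0):
        raise InputError("confusion matrix must be non-negative 3x3")
    i = LABEL_ORDER.index(SentimentLabel(cls))
    total = cm.sum()
    tp = cm[i, i]
    fn = cm[i, :].sum() - tp
    fp = cm[:, i].sum() - tp
    tn = total - tp - fn - fp
    sens = _ratio(tp, tp + fn)
    prec = _ratio(tp, tp + fp)
    acc = _ratio(tp + tn, total)
    if isnan(sens) or isnan(prec) or (sens + prec) == 0:
        f1 = nan
    else:
        f1 = 2 * sens * prec / (sens + prec)
    undefined = frozenset(
        name
        for name, value in (
            ("sensitivity", sens),
            ("precision", prec),
            ("accuracy", acc),
            ("f1", f1),
        )
        if isnan(value)
    )
    return ClassMetrics(sens, prec, acc, f1, undefined)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total: the fraction of exactly matched records."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total < 1:
        raise InputError("empty confusion matrix")
    return float(np.trace(cm) / total)


def cohen_kappa(rater_a: Sequence, rater_b: Sequence) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e)/(1 - p_e).

    Returns NaN for the degenerate case p_e = 1 (both raters constant and
    identical), where the statistic is undefined.
    """
    a = _as_values(rater_a)
    b = _as_values(rater_b)
    if len(a) != len(b) or not a:
        raise InputError("rater sequences must have equal nonzero length")
    if len(set(a)) == 1 and a == b:
        return nan
    return float(cohen_kappa_score(a, b, labels=_LABEL_VALUES))


def fuse_records(
    prob_tables: Mapping[str, pd.DataFrame],
    models: Sequence[str],
    discount: float = 1.0,
) -> pd.DataFrame:
    """Fuse per-record probability vectors from several models via Dempster
    combination.

    prob_tables maps model name -> DataFrame indexed by record id with
    columns p_negative, p_neutral, p_positive. Returns one row per record id
    (the intersection of all tables, in first-table order) with columns
    m_negative, m_neutral, m_positive, m_theta, conflict, decision, tie_flag.
    Records whose combination totally conflicts get decision NaN and
    tie_flag NaN with conflict 1.0.
    """
    if not models:
        raise InputError("need at least one model to fuse")
    missing = [m for m in models if m not in prob_tables]
    if missing:
        raise InputError(f"unknown model name(s): {missing}")
    tables = [prob_tables[m] for m in models]
    ids = tables[0].index
    for t in tables[1:]:
        ids = ids.intersection(t.index, sort=False)
    cols = ["p_negative", "p_neutral", "p_positive"]
    mats = [t.loc[ids, cols].to_numpy(dtype=float) for t in tables]
    rows = []
    for k, rid in enumerate(ids):
        bbas = [bba_from_probs(validate_probs(mat[k]), discount) for mat in mats]
        try:
            res = combine_all(bbas, sources=models)
        except TotalConflictError:
            rows.append((rid, nan, nan, nan, nan, 1.0, None, None))
            continue
        m = res.combined
        d = decide(m)
        rows.append(
            (rid, m[1], m[2], m[4], m[7], res.conflict, d.label.value, d.tie)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "m_negative",
            "m_neutral",
            "m_positive",
            "m_theta",
            "conflict",
            "decision",
            "tie_flag",
        ],
    ).set_index("id")


def sweep_combinations(
    prob_tables: Mapping[str, pd.DataFrame],
    gold: Mapping[str, SentimentLabel] | pd.Series,
    subsets: Sequence[Sequence[str]],
    discount: float = 1.0,
    include_singletons: bool = True,
) -> pd.DataFrame:
    """Score DST-fused model subsets (and each individual model) against gold.

    For each subset the per-record BBAs are combined, decided, and scored by
    overall accuracy. Totally conflicted records are excluded from the
    accuracy denominator and counted in ``n_conflict``. Returns a DataFrame
    with columns subset, n_scored, n_conflict, accuracy, accuracy_pct.
    """
    gold = pd.Series(
        {k: SentimentLabel(v).value for k, v in dict(gold).items()}
        if not isinstance(gold, pd.Series)
        else gold.map(lambda v: SentimentLabel(v).value)
    )
    wanted: list[tuple[str, ...]] = []
    if include_singletons:
        names_used = sorted({m for sub in subsets for m in sub})
        wanted.extend((m,) for m in names_used)
    wanted.extend(tuple(sub) for sub in subsets if len(sub) != 1 or tuple(sub) not in wanted)
    out = []
    for sub in wanted:
        unknown = [m for m in sub if m not in prob_tables]
        if unknown:
            raise InputError(f"subset references unregistered model(s): {unknown}")
        fused = fuse_records(prob_tables, list(sub), discount)
        fused = fused.loc[fused.index.intersection(gold.index, sort=False)]
        conflicted = fused["decision"].isna()
        scored = fused.loc[~conflicted]
        n_scored = len(scored)
        acc = (
            float((scored["decision"] == gold.loc[scored.index]).mean())
            if n_scored
            else nan
        )
        out.append(
            {
                "subset": "+".join(sub),
                "n_scored": n_scored,
                "n_conflict": int(conflicted.sum()),
                "accuracy": acc,
                "accuracy_pct": format_pct(acc) if n_scored else nan,
            }
        )
    return pd.DataFrame(
        out, columns=["subset", "n_scored", "n_conflict", "accuracy", "accuracy_pct"]
    )


def format_pct(proportion: float, decimals: int = 1) -> float:
    """Display percentage, rounded half-away-from-zero to ``decimals``."""
    if isnan(proportion):
        return nan
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(proportion * 100)).quantize(q, rounding=ROUND_HALF_UP))
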