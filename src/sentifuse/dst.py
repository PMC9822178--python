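"""Dempster-Shafer evidence theory on the three-class sentiment frame.

The frame of discernment is the fixed hypothesis set
Θ = (negative, neutral, positive). Evidence from one classifier is a *basic
belief assignment* (BBA): a mass function m over the 8 subsets of Θ with
m(∅) = 0 and Σ_{η ⊆ Θ} m(η) = 1; subsets with positive mass are the focal
elements. The *belief* committed to a subset ζ is the total mass of its
nonempty subsets, bel(ζ) = Σ_{∅ ≠ η ⊆ ζ} m(η).

Two BBAs are combined by Dempster's rule (the orthogonal sum): masses of
intersecting focal-element pairs multiply and accumulate on the
intersection, and the product mass K that lands on the empty set — the
*conflict* — is removed by normalising with 1/(1 − K). The rule is
commutative and associative, with the vacuous BBA m(Θ) = 1 as identity.
Total conflict (K → 1) is surfaced as an error, never silently
renormalised.

Representation: a BBA is a length-8 ``numpy`` array indexed by subset
bitmask — bit 0 = negative, bit 1 = neutral, bit 2 = positive — so index 0
is ∅ and index 7 is Θ. The frame is deliberately fixed at three classes;
clarity over generality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .corpus import LABEL_ORDER, SentimentLabel
from .errors import InputError, TotalConflictError

__all__ = [
    "EMPTY",
    "THETA",
    "SINGLETONS",
    "BBA",
    "CombinationResult",
    "Decision",
    "vacuous",
    "bba_from_probs",
    "validate_bba",
    "belief",
    "combine",
    "combine_all",
    "decide",
]

EMPTY = 0
THETA = 7
#: singleton bitmasks in canonical order (negative, neutral, positive)
SINGLETONS = (1, 2, 4)

_CONFLICT_EPS = 1e-12

BBA = np.ndarray  # length-8 mass vector over the powerset


def vacuous() -> BBA:
    """The total-ignorance BBA: all mass on Θ; identity of combination."""
    m = np.zeros(8)
    m[THETA] = 1.0
    return m


def validate_bba(m: Sequence[float], atol: float = 1e-9) -> BBA:
    m = np.asarray(m, dtype=float)
    if m.shape != (8,):
        raise InputError(f"a BBA is a length-8 mass vector, got shape {m.shape}")
    if abs(m[EMPTY]) > atol:
        raise InputError(f"m(empty set) must be 0, got {m[EMPTY]}")
    if np.any(m < -atol):
        raise InputError("masses must be non-negative")
    if abs(m.sum() - 1.0) > 1e-6:
        raise InputError(f"masses sum to {m.sum()}, not 1")
    out = np.clip(m, 0.0, None)
    out[EMPTY] = 0.0
    return out


def bba_from_probs(p: Sequence[float], discount: float = 1.0) -> BBA:
    """Embed a classifier probability vector as a BBA.

    Singleton focal elements get ``discount * p_c``; the reliability
    remainder ``1 - discount`` goes to Θ (classical discounting). With
    discount 1 this is the bare probability embedding, under which Dempster
    combination reduces to a normalised product rule.
    """
    from .backends import validate_probs

    if not 0 < discount <= 1:
        raise InputError("discount must lie in (0, 1]")
    p = validate_probs(p)
    m = np.zeros(8)
    for mask, prob in zip(SINGLETONS, p):
        m[mask] = discount * prob
    m[THETA] = 1.0 - discount
    return m


def belief(m: Sequence[float], subset: int) -> float:
    """bel(ζ): total mass of the nonempty subsets of ζ."""
    if subset == EMPTY:
        raise InputError("belief of the empty set is not defined")
    if not 0 < subset <= THETA:
        raise InputError(f"subset bitmask out of range: {subset}")
    m = np.asarray(m, dtype=float)
    return float(sum(m[s] for s in range(1, 8) if s & subset == s))


@dataclass
class CombinationResult:
    """Outcome of an orthogonal sum: the combined BBA, the conflict mass K
    removed by normalisation, and the names of the combined sources."""

    combined: BBA
    conflict: float
    sources: tuple[str, ...] = ()


def combine(
    m1: Sequence[float],
    m2: Sequence[float],
    sources: tuple[str, str] = ("m1", "m2"),
) -> CombinationResult:
    """Dempster's rule for two BBAs.

    For every nonempty ϑ ⊆ Θ the combined mass is
    Σ {m1(η)·m2(ζ) : η ∩ ζ = ϑ} / (1 − K), with K the total product mass on
    empty intersections. K within 1e-12 of 1 raises
    :class:`~sentifuse.errors.TotalConflictError`.
    """
    m1 = validate_bba(m1)
    m2 = validate_bba(m2)
    acc = np.zeros(8)
    for a in range(1, 8):
        if m1[a] == 0.0:
            continue
        for b in range(1, 8):
            if m2[b] == 0.0:
                continue
            acc[a & b] += m1[a] * m2[b]
    conflict = acc[EMPTY]
    if conflict >= 1.0 - _CONFLICT_EPS:
        raise TotalConflictError(sources=sources)
    combined = np.zeros(8)
    combined[1:] = acc[1:] / (1.0 - conflict)
    return CombinationResult(combined, float(conflict), sources)


def combine_all(
    bbas: Iterable[Sequence[float]], sources: Sequence[str] | None = None
) -> CombinationResult:
    """Left fold of Dempster's rule over one or more BBAs.

    The combined masses are independent of input order (the rule is
    commutative and associative). The reported conflict is the global
    normalisation deficit 1 − Π(1 − K_step), likewise order-invariant. A
    degenerate pairwise step raises a conflict error naming the step.
    """
    bbas = [validate_bba(m) for m in bbas]
    if not bbas:
        raise InputError("combine_all needs at least one BBA")
    names = tuple(sources) if sources else tuple(f"m{i+1}" for i in range(len(bbas)))
    if len(names) != len(bbas):
        raise InputError("sources must match the number of BBAs")
    acc = bbas[0]
    kept = 1.0  # running product of (1 - K_step)
    for step, m in enumerate(bbas[1:], start=1):
        try:
            res = combine(acc, m, sources=(names[0] if step == 1 else "partial", names[step]))
        except TotalConflictError:
            raise TotalConflictError(sources=names, step=step) from None
        acc = res.combined
        kept *= 1.0 - res.conflict
    return CombinationResult(acc, float(1.0 - kept), names)


@dataclass(frozen=True)
class Decision:
    """Final label choice from a fused BBA; ``tie`` marks a broken tie."""

    label: SentimentLabel
    tie: bool = False


def decide(m: Sequence[float], atol: float = 1e-12) -> Decision:
    """Pick the sentiment with maximal singleton belief.

    For singleton-focal BBAs this equals max mass. Ties (within ``atol``)
    break toward the canonical order negative < neutral < positive and are
    flagged.
    """
    m = validate_bba(m)
    beliefs = np.array([belief(m, s) for s in SINGLETONS])
    best = int(np.argmax(beliefs))
    tie = bool(np.sum(beliefs >= beliefs[best] - atol) > 1)
    return Decision(LABEL_ORDER[best], tie)
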