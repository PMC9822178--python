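"""Probabilistic sentiment-classifier backends.

Every backend, real or simulated, honours one contract: given a text it
returns a probability vector over (negative, neutral, positive) that sums
to one. Two kinds exist:

* ``external_adapter`` — a hook for pretrained models (e.g. transformer
  sentiment heads). The adapter takes a user-supplied ``predict_fn`` callable
  returning either a 3-vector or a 5-star review-score vector; no model
  weights ship with the package, and without a callable the backend raises
  :class:`~sentifuse.errors.BackendUnavailableError`.
* ``mock`` — a synthetic noisy classifier defined by a 3x3 row-stochastic
  confusion matrix over the true label and a Dirichlet concentration that
  controls how sharp its probability outputs are. Mocks are the testing
  stand-in for external models and the source of conditionally independent
  ensembles in simulations.

Five-star review scores (1..5 stars) are folded to three classes by the
standard mapping: fewer than 3 stars is negative, exactly 3 is neutral,
4 or more is positive.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .corpus import LABEL_ORDER, SentimentLabel
from .errors import BackendUnavailableError, InputError

__all__ = [
    "ProbVector",
    "MockParams",
    "ClassifierSpec",
    "validate_probs",
    "map_five_star_to_three",
    "mock_classify",
    "mock_classify_batch",
    "classify",
]

#: a probability vector is any length-3 array-like over (neg, neu, pos)
ProbVector = np.ndarray

_ATOL = 1e-9


def validate_probs(p: Sequence[float], length: int = 3) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (length,):
        raise InputError(f"expected a length-{length} probability vector, got shape {p.shape}")
    if np.any(p < -_ATOL) or np.any(p > 1 + _ATOL):
        raise InputError(f"probabilities outside [0, 1]: {p}")
    if abs(p.sum() - 1.0) > 1e-6:
        raise InputError(f"probabilities sum to {p.sum()}, not 1")
    return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class MockParams:
    """Parameters of a synthetic noisy classifier.

    confusion: 3x3 row-stochastic matrix; row = true label, column = the
    predicted tendency drawn for a record with that true label.
    concentration: Dirichlet sharpness of the emitted probability vector
    around the drawn tendency (larger = closer to a one-hot output).
    """

    confusion: tuple = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )
    concentration: float = 20.0
    seed: int = 0

    def matrix(self) -> np.ndarray:
        m = np.asarray(self.confusion, dtype=float)
        if m.shape != (3, 3) or np.any(m < 0):
            raise InputError("confusion must be a non-negative 3x3 matrix")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise InputError("confusion rows must each sum to 1")
        if self.concentration <= 0:
            raise InputError("concentration must be positive")
        return m

    @classmethod
    def symmetric(cls, accuracy: float, concentration: float = 20.0, seed: int = 0) -> "MockParams":
        """Confusion with ``accuracy`` on the diagonal and the remainder split
        evenly between the two wrong classes."""
        if not 0 < accuracy <= 1:
            raise InputError("accuracy must be in (0, 1]")
        off = (1.0 - accuracy) / 2.0
        row = lambda i: tuple(accuracy if j == i else off for j in range(3))
        return cls(confusion=(row(0), row(1), row(2)), concentration=concentration, seed=seed)


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier in an ensemble: either an external adapter or a mock."""

    name: str
    kind: str = "mock"  # {"external_adapter", "mock"}
    mock: Optional[MockParams] = None
    predict_fn: Optional[Callable[[str], Sequence[float]]] = field(
        default=None, compare=False
    )

    def __post_init__(self):
        if self.kind not in ("external_adapter", "mock"):
            raise InputError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "mock" and self.mock is None:
            object.__setattr__(self, "mock", MockParams())


def map_five_star_to_three(stars: Sequence[float]) -> np.ndarray:
    """Fold a 5-star review-score distribution onto three sentiment classes:
    p(neg) = s1 + s2, p(neu) = s3, p(pos) = s4 + s5."""
    s = validate_probs(stars, length=5)
    return np.array([s[0] + s[1], s[2], s[3] + s[4]])


def _dirichlet_around(
    label_index: np.ndarray, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw simplex points concentrated on the given class indices.

    Dirichlet with alpha_j = 1 + concentration * [j == label]; the mean puts
    (1 + c) / (3 + c) on the tendency class, approaching a one-hot vector as
    c grows and the uniform simplex distribution as c -> 0.
    """
    n = label_index.shape[0]
    alpha = np.ones((n, 3))
    alpha[np.arange(n), label_index] += concentration
    draws = rng.gamma(shape=alpha)
    return draws / draws.sum(axis=1, keepdims=True)


def mock_classify_batch(
    gold: Sequence[SentimentLabel],
    params: MockParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Vectorised mock classification of many records at once.

    For each record the predicted tendency is drawn from the confusion row of
    its gold label, then the emitted probability vector is drawn from a
    Dirichlet centred on that tendency. Rows of the result are valid
    probability vectors; conditionally independent across records.
    """
    confusion = params.matrix()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    gold_idx = np.array([LABEL_ORDER.index(SentimentLabel(g)) for g in gold])
    u = rng.random(gold_idx.shape[0])
    cum = np.cumsum(confusion, axis=1)[gold_idx]
    tendency = (u[:, None] > cum).sum(axis=1)
    return _dirichlet_around(tendency, params.concentration, rng)


def mock_classify(
    gold: SentimentLabel,
    params: MockParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Classify one record with a mock backend; reproducible under a fixed
    seed (or an explicitly supplied generator)."""
    return mock_classify_batch([gold], params, rng)[0]


def _stable_text_seed(text: str, base_seed: int) -> int:
    # crc32 gives a platform-stable digest; keep the combined seed < 2^31
    return (base_seed * 1_000_003 + zlib.crc32(text.encode("utf-8"))) % (2**31 - 1)


def classify(
    text: str,
    spec: ClassifierSpec,
    gold: Optional[SentimentLabel] = None,
) -> np.ndarray:
    """Classify a text under the uniform backend contract.

    Deterministic for a fixed spec and text: the mock path seeds its generator
    from the spec seed and a stable digest of the text. The mock kind needs a
    gold label (it simulates a classifier of known confusion); the external
    adapter forwards to its ``predict_fn`` and folds 5-star outputs to three
    classes when needed.
    """
    if not text or not text.strip():
        raise InputError("cannot classify empty text")
    if spec.kind == "external_adapter":
        if spec.predict_fn is None:
            raise BackendUnavailableError(
                f"classifier {spec.name!r} has no model attached; supply "
                "predict_fn or use a mock classifier (kind='mock')"
            )
        out = np.asarray(spec.predict_fn(text), dtype=float)
        if out.shape == (5,):
            return map_five_star_to_three(out)
        return validate_probs(out)
    if gold is None:
        raise InputError("mock classification requires a gold label")
    rng = np.random.default_rng(_stable_text_seed(text, spec.mock.seed))
    return mock_classify(gold, spec.mock, rng)
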