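"""ADMET-based screening of an herbal compound library.

The screen works on signed class probabilities as produced by
admetSAR-style classifiers: the sign encodes the predicted class
(positive = absorbable / CYP inhibitor), the magnitude encodes the
classifier's confidence. Two rules are applied:

1. absorption — a compound is kept only if both its human intestinal
   absorption (HIA) and Caco-2 permeability predictions are strictly
   positive;
2. metabolism — the five CYP450 inhibition predictions (isoforms 1A2,
   2C9, 2D6, 2C19, 3A4, in that column order) are combined into a single
   composite score, a dot product with each isoform's overall predictive
   accuracy Q; compounds whose composite score is not above the floor
   (default 0) are discarded.

The composite score is ``score = sum_k cyp_k * q_k`` with signed inputs
contributing with their sign, so a confident non-inhibitor prediction
pulls the score down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

from .errors import ValidationError

#: Overall predictive accuracies (Q) of the five CYP isoform classifiers,
#: applied positionally to the CYP columns in the order 1A2, 2C9, 2D6,
#: 2C19, 3A4.
DEFAULT_CYP_ACCURACIES: Tuple[float, ...] = (0.8147, 0.8018, 0.8551, 0.8054, 0.6450)

#: CYP isoform column order used throughout the package.
CYP_ISOFORMS: Tuple[str, ...] = ("1a2", "2c9", "2d6", "2c19", "3a4")

N_CYP = 5

#: Discard reason codes used by :func:`screen_library`.
REASON_ABSORPTION = "absorption"
REASON_SCORE = "score"


def _check_signed_probability(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if abs(value) > 1.0:
        raise ValidationError(f"{name} must lie in [-1, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class CypWeights:
    """Per-isoform predictive accuracies used as composite-score weights.

    The five entries are applied positionally to the CYP columns in
    table order (1A2, 2C9, 2D6, 2C19, 3A4).
    """

    q: Tuple[float, ...] = DEFAULT_CYP_ACCURACIES

    def __post_init__(self) -> None:
        q = tuple(float(v) for v in self.q)
        if len(q) != N_CYP:
            raise ValidationError(f"expected {N_CYP} weights, got {len(q)}")
        for v in q:
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"weights must be finite and > 0, got {v!r}")
        object.__setattr__(self, "q", q)


@dataclass(frozen=True)
class CompoundADMETRecord:
    """One compound's signed ADMET class probabilities.

    ``cyp`` holds the five CYP inhibition predictions in table column
    order (1A2, 2C9, 2D6, 2C19, 3A4). ``score`` is filled in by
    :func:`screen_library` (or may be pre-set).
    """

    compound_id: str
    hia: float
    caco2: float
    cyp: Tuple[float, ...]
    herb: Optional[str] = None
    smiles: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        object.__setattr__(self, "hia", _check_signed_probability("hia", self.hia))
        object.__setattr__(self, "caco2", _check_signed_probability("caco2", self.caco2))
        cyp = tuple(float(v) for v in self.cyp)
        if len(cyp) != N_CYP:
            raise ValidationError(
                f"{self.compound_id}: expected {N_CYP} CYP entries, got {len(cyp)}"
            )
        cyp = tuple(
            _check_signed_probability(f"cyp[{i}]", v) for i, v in enumerate(cyp)
        )
        object.__setattr__(self, "cyp", cyp)

    def scored(self, weights: CypWeights) -> "CompoundADMETRecord":
        """Return a copy carrying its composite CYP score."""
        return replace(self, score=cyp_composite_score(self.cyp, weights))


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of screening a library: retained/discarded partition."""

    retained: Tuple[CompoundADMETRecord, ...]
    discarded: Tuple[Tuple[CompoundADMETRecord, str], ...]
    rules_applied: dict = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.discarded)


def cyp_composite_score(
    cyp: Sequence[float], weights: Optional[CypWeights] = None
) -> float:
    """Composite CYP-inhibition score: dot product of the five signed
    predictions with the per-isoform predictive accuracies.

    Parameters
    ----------
    cyp:
        Five signed probabilities in table column order (1A2, 2C9, 2D6,
        2C19, 3A4), each in [-1, 1].
    weights:
        Per-isoform accuracies; defaults to :data:`DEFAULT_CYP_ACCURACIES`.
    """
    if weights is None:
        weights = CypWeights()
    cyp = tuple(float(v) for v in cyp)
    if len(cyp) != N_CYP:
        raise ValidationError(f"expected {N_CYP} CYP entries, got {len(cyp)}")
    for i, v in enumerate(cyp):
        _check_signed_probability(f"cyp[{i}]", v)
    return float(sum(c * q for c, q in zip(cyp, weights.q)))


def passes_absorption(record: CompoundADMETRecord) -> bool:
    """True iff both absorption endpoints are predicted positive.

    Strict positivity: a probability of exactly 0 fails the filter.
    """
    return record.hia > 0.0 and record.caco2 > 0.0


def screen_library(
    records: Iterable[CompoundADMETRecord],
    weights: Optional[CypWeights] = None,
    score_floor: float = 0.0,
) -> ScreenResult:
    """Apply the absorption filter then the composite-score filter.

    A record is retained iff ``passes_absorption`` is true and its
    composite score is strictly greater than ``score_floor``. Discarded
    records carry a reason code (``"absorption"`` or ``"score"``); the
    absorption rule is checked first, so a record failing both is
    attributed to absorption.
    """
    if weights is None:
        weights = CypWeights()
    retained = []
    discarded = []
    for record in records:
        scored = record.scored(weights)
        if not passes_absorption(scored):
            discarded.append((scored, REASON_ABSORPTION))
        elif scored.score <= score_floor:
            discarded.append((scored, REASON_SCORE))
        else:
            retained.append(scored)
    return ScreenResult(
        retained=tuple(retained),
        discarded=tuple(discarded),
        rules_applied={
            "weights": weights.q,
            "score_floor": float(score_floor),
            "absorption": "hia > 0 and caco2 > 0",
        },
    )


def rank_compounds(
    result: ScreenResult, key: str = "score"
) -> Tuple[CompoundADMETRecord, ...]:
    """Order retained compounds for reporting.

    ``key="score"`` sorts by descending composite score with ties broken
    lexicographically by compound id; ``key="compound_id"`` sorts by id.
    """
    if key == "score":
        for r in result.retained:
            if r.score is None:
                raise ValidationError(f"{r.compound_id} has no score")
        return tuple(
            sorted(result.retained, key=lambda r: (-r.score, r.compound_id))
        )
    if key == "compound_id":
        return tuple(sorted(result.retained, key=lambda r: r.compound_id))
    raise ValidationError(f"unknown ranking key {key!r}")


def pass_rate(n_passed: int, n_total: int) -> float:
    """Percentage of a library passing a filter, at full precision."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_passed <= n_total:
        raise ValidationError("n_passed must lie in [0, n_total]")
    return 100.0 * n_passed / n_total
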