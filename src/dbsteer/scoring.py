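"""Symptom weighting, selection and the total weighted score.

Each lateralized symptom is scored 0-4 (0.1 resolution) by a clinician or
a wearable sensor.  A symptom's weight combines its untreated severity and
its relative improvement under therapy::

    w = (delta / 4) * (delta / baseline_off),   delta = off - on

quantized to 0.001.  The weight is zero for symptoms that do not improve.
The published description of the weighting is proprietary; this product
form is an assumption that exactly reproduces the three documented worked
examples (4->0 gives 1.0, 2->0 gives 0.50, 2->1 gives 0.125).

The top-weighted symptoms (at most four per hemisphere) are kept and their
weights renormalized to sum to 1; the scalar optimizer feedback is the
weighted sum of the per-step symptom scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

SCORE_MIN = 0.0
SCORE_MAX = 4.0
WEIGHT_RESOLUTION = 0.001

_SOURCE_RANK = {"clinician": 0, "sensor": 1}


class NoResponsiveSymptomsError(ValueError):
    """All candidate symptoms have zero weight."""


def _check_score(value: float, name: str) -> float:
    value = float(value)
    if not SCORE_MIN <= value <= SCORE_MAX:
        raise ValueError(f"{name}={value} outside [{SCORE_MIN}, {SCORE_MAX}]")
    return value


def compute_weight(baseline_off: float, baseline_on: float) -> float:
    """Raw symptom weight in [0, 1] from the two baseline assessments.

    Zero when the symptom is absent (``baseline_off == 0``) or does not
    improve; otherwise ``delta**2 / (4 * baseline_off)`` rounded to 0.001.
    """
    off = _check_score(baseline_off, "baseline_off")
    on = _check_score(baseline_on, "baseline_on")
    delta = off - on
    if off <= 0.0 or delta <= 0.0:
        return 0.0
    w = (delta / 4.0) * (delta / off)
    w = min(max(w, 0.0), 1.0)
    return round(w / WEIGHT_RESOLUTION) * WEIGHT_RESOLUTION


@dataclass(frozen=True)
class SymptomAssessment:
    """Baseline assessment of one lateralized symptom."""

    name: str
    laterality: str = ""
    source: str = "clinician"
    baseline_off: float = 0.0
    baseline_on: float = 0.0

    def __post_init__(self) -> None:
        if self.source not in _SOURCE_RANK:
            raise ValueError(f"source must be clinician or sensor, got {self.source!r}")
        _check_score(self.baseline_off, "baseline_off")
        _check_score(self.baseline_on, "baseline_on")

    @property
    def symptom_id(self) -> str:
        return f"{self.name}|{self.laterality}" if self.laterality else self.name

    @property
    def improved(self) -> bool:
        return self.baseline_on <= self.baseline_off

    @property
    def weight(self) -> float:
        # Worsening under therapy is flagged by zero weight, not an error.
        if not self.improved:
            return 0.0
        return compute_weight(self.baseline_off, self.baseline_on)


@dataclass(frozen=True)
class WeightedScoreSpec:
    """Selected symptoms with raw and normalized weights (summing to 1)."""

    symptoms: tuple[SymptomAssessment, ...]
    raw_weights: tuple[float, ...]
    normalized_weights: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.symptoms)
        if not (len(self.raw_weights) == len(self.normalized_weights) == n):
            raise ValueError("weight tuples must align with symptoms")
        if n == 0:
            raise ValueError("a score spec needs at least one symptom")
        total = sum(self.normalized_weights)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"normalized weights sum to {total}, not 1")

    @property
    def symptom_ids(self) -> tuple[str, ...]:
        return tuple(a.symptom_id for a in self.symptoms)


def select_symptoms(
    assessments: Sequence[SymptomAssessment], max_n: int = 4
) -> WeightedScoreSpec:
    """Rank assessments by weight and keep the top ``max_n``.

    Ties are broken clinician-before-sensor, then lexically by symptom id.
    Raises :class:`NoResponsiveSymptomsError` when every weight is zero.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    weighted = [(a.weight, a) for a in assessments]
    positive = [(w, a) for w, a in weighted if w > 0.0]
    if not positive:
        raise NoResponsiveSymptomsError("no responsive symptoms")
    positive.sort(key=lambda wa: (-wa[0], _SOURCE_RANK[wa[1].source], wa[1].symptom_id))
    kept = positive[:max_n]
    raw = tuple(w for w, _ in kept)
    total = sum(raw)
    return WeightedScoreSpec(
        symptoms=tuple(a for _, a in kept),
        raw_weights=raw,
        normalized_weights=tuple(w / total for w in raw),
    )


def total_weighted_score(
    spec: WeightedScoreSpec,
    scores: Mapping[str, float],
    side_effect: bool = False,
) -> tuple[float, bool]:
    """Collapse per-symptom scores into the scalar optimizer feedback.

    ``scores`` maps symptom ids to 0-4 values; the side-effect flag is
    passed through unchanged for boundary handling downstream.
    """
    total = 0.0
    for assessment, w in zip(spec.symptoms, spec.normalized_weights):
        key = assessment.symptom_id
        if key not in scores:
            raise KeyError(f"missing score for symptom {key!r}")
        total += w * _check_score(scores[key], key)
    return total, side_effect
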