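"""Linear scoring tables for meningioma WHO grade and surgical consistency.

A scoring table is a published (or re-derived) linear decision rule: the
score S = sum_i w_i * x_i over raw feature values is compared against a
threshold T, with score > T assigning the positive class (WHO grade 2 for
the grade model, soft consistency for the consistency model) and score < T
the negative class.  Weights are averaged bootstrapped logistic-regression
coefficients with the continuous-variable scaling folded back onto raw
units, so they apply directly to years, cm^3 and unitless FD/LI values.

The two packaged tables ship the published weights and thresholds:

* grade:       S = 0.312*FD - 0.009*age - 1.645*homogeneous_enhancement
               + 0.004*tumor_volume, threshold -3.114
* consistency: S = 0.446*LI - 1.020*homogeneous_enhancement, threshold 0.003

where homogeneous_enhancement is 0/1 and LI is the FLAIR-sequence
lacunarity index by convention.  exp(weight) should reproduce each row's
published odds ratio; :func:`self_check` verifies this and flags the one
row where the published OR equals exp(-weight) instead (a sign
inconsistency in the source table, reported rather than silently fixed).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .exceptions import MissingFeatureError, ValidationError

logger = logging.getLogger(__name__)

_BINARY_VARIABLES = {"homogeneous_enhancement"}


@dataclass(frozen=True)
class ScoringTable:
    """A named linear decision rule: sum of weight * raw feature vs threshold."""

    name: str
    terms: tuple[tuple[str, float], ...]
    threshold: float
    positive_class: str
    negative_class: str
    tie_class: str | None = None
    reported_ors: tuple[float | None, ...] = ()

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError("scoring table needs >= 1 term")
        names = [v for v, _ in self.terms]
        if len(set(names)) != len(names):
            raise ValidationError("scoring-table variable names must be unique")
        if self.positive_class == self.negative_class:
            raise ValidationError("class labels must be distinct")
        if self.tie_class is None:
            object.__setattr__(self, "tie_class", self.negative_class)
        if not self.reported_ors:
            object.__setattr__(self, "reported_ors", (None,) * len(self.terms))
        elif len(self.reported_ors) != len(self.terms):
            raise ValidationError("reported_ors must align with terms")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(v for v, _ in self.terms)

    def to_dict(self) -> dict:
        terms = []
        for (var, w), ror in zip(self.terms, self.reported_ors):
            t = {"variable": var, "weight": w}
            if ror is not None:
                t["reported_or"] = ror
            terms.append(t)
        return {
            "name": self.name,
            "terms": terms,
            "threshold": self.threshold,
            "positive_class": self.positive_class,
            "negative_class": self.negative_class,
        }

    def to_json(self) -> str:
        """Canonical JSON serialization (stable byte-for-byte round trips)."""
        return json.dumps(self.to_dict(), indent=2) + "\n"

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringTable":
        return cls(
            name=d["name"],
            terms=tuple((t["variable"], float(t["weight"])) for t in d["terms"]),
            threshold=float(d["threshold"]),
            positive_class=d["positive_class"],
            negative_class=d["negative_class"],
            reported_ors=tuple(
                float(t["reported_or"]) if "reported_or" in t else None
                for t in d["terms"]
            ),
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoringTable":
        return cls.from_dict(json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ScoringTable":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class GradeFeatures:
    """Raw inputs to the WHO-grade score."""

    fd: float
    age: float
    homogeneous_enhancement: int
    tumor_volume: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        if self.tumor_volume <= 0:
            raise ValidationError(f"tumor_volume must be positive, got {self.tumor_volume}")

    def to_dict(self) -> dict[str, float]:
        return {
            "fd": self.fd,
            "age": self.age,
            "homogeneous_enhancement": self.homogeneous_enhancement,
            "tumor_volume": self.tumor_volume,
        }


@dataclass(frozen=True)
class ConsistencyFeatures:
    """Raw inputs to the consistency score (LI from FLAIR by default)."""

    li: float
    homogeneous_enhancement: int

    def to_dict(self) -> dict[str, float]:
        return {"li": self.li, "homogeneous_enhancement": self.homogeneous_enhancement}


@dataclass(frozen=True)
class ScoreResult:
    score: float
    predicted_class: str
    table_name: str
    term_contributions: tuple[tuple[str, float], ...]


def packaged_tables() -> tuple[ScoringTable, ScoringTable]:
    """The published grade and consistency scoring tables shipped with the package."""
    pkg = resources.files("voxfract") / "tables"
    grade = ScoringTable.from_json((pkg / "grade.json").read_text())
    consistency = ScoringTable.from_json((pkg / "consistency.json").read_text())
    return grade, consistency


def score(
    features: GradeFeatures | ConsistencyFeatures | Mapping[str, float],
    table: ScoringTable,
) -> ScoreResult:
    """Apply a scoring table to raw feature values.

    score > threshold assigns the positive class, score < threshold the
    negative class; exact equality assigns the tie class (the negative class
    by default) with a logged warning.
    """
    values = features.to_dict() if hasattr(features, "to_dict") else dict(features)
    contributions = []
    total = 0.0
    for var, w in table.terms:
        if var not in values:
            raise MissingFeatureError(
                f"feature {var!r} required by table {table.name!r} is missing"
            )
        x = float(values[var])
        if var in _BINARY_VARIABLES and x not in (0.0, 1.0):
            raise ValidationError(f"{var} must be 0 or 1, got {values[var]!r}")
        contributions.append((var, w * x))
        total += w * x
    if total > table.threshold:
        cls = table.positive_class
    elif total < table.threshold:
        cls = table.negative_class
    else:
        cls = table.tie_class
        logger.warning(
            "score exactly equals threshold %s; assigning tie class %r",
            table.threshold,
            cls,
        )
    return ScoreResult(
        score=total,
        predicted_class=cls,
        table_name=table.name,
        term_contributions=tuple(contributions),
    )


def weight_to_or(table: ScoringTable) -> list[tuple[str, float]]:
    """Per-unit odds ratios exp(w_i) implied by the table weights."""
    return [(var, math.exp(w)) for var, w in table.terms]


def self_check(table: ScoringTable) -> list[dict]:
    """Compare exp(weight) with the published odds ratio for each term.

    Returns one record per term with the implied OR, the published OR (if
    recorded) and whether they agree to 3 decimals.  A mismatch is reported,
    not corrected: the published grade-model FD row prints exp(-weight).
    """
    report = []
    for (var, w), ror in zip(table.terms, table.reported_ors):
        implied = math.exp(w)
        entry = {
            "table": table.name,
            "variable": var,
            "weight": w,
            "implied_or": implied,
            "reported_or": ror,
            "consistent": None if ror is None else round(implied, 3) == round(ror, 3),
        }
        if entry["consistent"] is False:
            logger.warning(
                "table %r row %r: exp(weight)=%.3f does not match reported OR %.3f",
                table.name,
                var,
                implied,
                ror,
            )
        report.append(entry)
    return report
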