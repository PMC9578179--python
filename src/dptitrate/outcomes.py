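"""Physiological and histological outcome computations.

Covers the three outcome primitives of a ventilator-induced-lung-injury
experiment: the PaO2/FiO2 oxygenation ratio, ARDS severity under the Berlin
definition, and the four-item ALI histology score (alveolar capillary
congestion, hemorrhage, neutrophil infiltration / alveolar-wall thickness,
hyaline membranes), each item rated 0–4 per rater, averaged across raters
and summed to a 0–16 global score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "ALI_ITEMS",
    "BloodGas",
    "AliRatings",
    "AliScore",
    "pf_ratio",
    "classify_berlin",
    "ali_aggregate",
]

#: the four ALI score items, in reporting order
ALI_ITEMS = (
    "congestion",
    "hemorrhage",
    "neutrophil_infiltration",
    "hyaline_membrane",
)


@dataclass(frozen=True)
class BloodGas:
    """One arterial blood-gas sample."""

    pao2: float  # mmHg
    fio2: float  # fraction of inspired oxygen, (0, 1]
    paco2: float = float("nan")  # mmHg
    lactate: float = float("nan")  # mmol/L
    peep_at_measurement: float = float("nan")  # cmH2O

    def __post_init__(self) -> None:
        if self.pao2 <= 0:
            raise ValueError("pao2 must be > 0")
        if not 0 < self.fio2 <= 1:
            raise ValueError("fio2 must be in (0, 1]")
        if self.paco2 == self.paco2 and self.paco2 <= 0:  # NaN-safe
            raise ValueError("paco2 must be > 0 when given")


@dataclass(frozen=True)
class AliRatings:
    """Per-rater 0–4 integer scores for the four ALI items of one sample."""

    subject_id: str
    ratings: Mapping[str, Mapping[str, int]]  # rater -> item -> score

    def __post_init__(self) -> None:
        if not self.ratings:
            raise ValueError("at least one rater is required")
        for rater, items in self.ratings.items():
            missing = set(ALI_ITEMS) - set(items)
            if missing:
                raise ValueError(f"rater {rater!r} is missing items {sorted(missing)}")
            extra = set(items) - set(ALI_ITEMS)
            if extra:
                raise ValueError(f"rater {rater!r} has unknown items {sorted(extra)}")
            for item, score in items.items():
                if score != int(score) or not 0 <= int(score) <= 4:
                    raise ValueError(
                        f"score for {rater!r}/{item!r} must be an integer in 0..4, got {score!r}"
                    )


@dataclass(frozen=True)
class AliScore:
    """Across-rater item means (0–4, possibly fractional) and their 0–16 sum."""

    subject_id: str
    item_means: Mapping[str, float]
    global_score: float


def pf_ratio(g: BloodGas) -> float:
    """PaO2/FiO2 ratio in mmHg."""
    return g.pao2 / g.fio2


def classify_berlin(pf: float, peep: float) -> str:
    """ARDS severity from the P/F ratio under the Berlin definition.

    Thresholds are inclusive on the upper edge of each class (pf = 100 is
    severe, 200 moderate, 300 mild).  Classification requires PEEP (or CPAP)
    of at least 5 cmH2O; below that the sample is not classifiable.
    """
    if pf <= 0:
        raise ValueError("pf must be > 0")
    if peep < 5:
        return "not_classifiable"
    if pf <= 100:
        return "severe"
    if pf <= 200:
        return "moderate"
    if pf <= 300:
        return "mild"
    return "none"


def ali_aggregate(r: AliRatings) -> AliScore:
    """Mean each item across raters and sum the four means (0–16 global)."""
    item_means = {
        item: sum(items[item] for items in r.ratings.values()) / len(r.ratings)
        for item in ALI_ITEMS
    }
    return AliScore(
        subject_id=r.subject_id,
        item_means=item_means,
        global_score=sum(item_means.values()),
    )
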