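"""The 0-100 overlap score.

A test disease is scored by its phenotype overlap with the positive
reference group relative to its overlap with the negative (control) group:

    score = 100 * O+ / (O+ + O-)

where O+ and O- are the mean prevalence-product overlaps with the diseases
of each group.  A score above 50 means the test phenotype overlaps the
positive group more than the controls; 100 means no control overlap at all.
Means (rather than sums) are used so unequal group sizes do not bias the
score.  A test profile sharing nothing with either group is maximally
uninformative and scores 50, flagged as ``no_overlap``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .phenodb import DiseaseProfile, PhenotypeMatrix

__all__ = ["ScoreReport", "overlap", "mito_score"]


@dataclass
class ScoreReport:
    score: float
    positive_overlap: float
    negative_overlap: float
    per_disease_overlap: dict[str, float] = field(default_factory=dict)
    no_overlap: bool = False

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "positive_overlap": self.positive_overlap,
            "negative_overlap": self.negative_overlap,
            "no_overlap": self.no_overlap,
            "per_disease_overlap": self.per_disease_overlap,
        }


def overlap(test: DiseaseProfile, other: DiseaseProfile) -> float:
    """Prevalence-product overlap of two diseases.

    Sum over shared parameters of p_test * p_other / 10000; each shared
    parameter contributes a term in [0, 1].
    """
    total = 0.0
    for param, p in test.prevalences.items():
        q = other.prevalences.get(param, 0.0)
        total += p * q
    return total / 10000.0


def mito_score(test: DiseaseProfile, matrix: PhenotypeMatrix) -> ScoreReport:
    """Score a test disease against the reference database.

    Requires both reference groups (positive and negative) to be non-empty.
    """
    per: dict[str, float] = {}
    sums = {"positive": 0.0, "negative": 0.0}
    counts = {"positive": 0, "negative": 0}
    col = {p: j for j, p in enumerate(matrix.parameters)}
    for name, group in zip(matrix.diseases, matrix.groups):
        if group not in sums:
            continue
        row = matrix.row(name)
        ov = sum(p * row[col[param]] for param, p in test.prevalences.items() if param in col)
        ov /= 10000.0
        per[name] = float(ov)
        sums[group] += ov
        counts[group] += 1
    for g in ("positive", "negative"):
        if counts[g] == 0:
            raise ValidationError(f"reference group {g!r} is empty")
    pos = sums["positive"] / counts["positive"]
    neg = sums["negative"] / counts["negative"]
    if pos + neg == 0:
        return ScoreReport(50.0, 0.0, 0.0, per, no_overlap=True)
    return ScoreReport(float(100.0 * pos / (pos + neg)), float(pos), float(neg), per)
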