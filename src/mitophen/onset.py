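"""Age-of-onset modelling.

Each disease may carry a mean age of onset and standard deviation (years).
The onset of a single clinical parameter is modelled as a Gaussian mixture
over the diseases showing that parameter, with mixture weights proportional
to the parameter's prevalence in each disease: a parameter seen mostly in
early-onset diseases gets an early-peaked density.  A disease with onset
standard deviation 0 contributes a point mass at its mean.

Splitting the database at an onset cutoff (default 20 years) yields early-
and late-onset sub-matrices whose group-mean phenotype profiles can be
compared by Pearson correlation: a high value says the early- and late-
onset diseases present an overall similar phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, pearsonr

from .errors import UndefinedSimilarityError, ValidationError
from .phenodb import DiseaseProfile, PhenotypeMatrix

__all__ = [
    "OnsetDensity",
    "onsets_from_profiles",
    "parameter_onset_density",
    "split_by_onset",
    "early_late_correlation",
]

Onsets = Mapping[str, tuple[float, float]]  # disease -> (mean years, sd years)


@dataclass
class OnsetDensity:
    """Prevalence-weighted Gaussian mixture for one parameter's onset age."""

    parameter: str
    components: list[tuple[str, float, float, float]]  # (disease, weight, mean, sd)

    def mean(self) -> float:
        """Closed-form mixture mean: sum of weight * component mean."""
        return float(sum(w * mu for _d, w, mu, _sd in self.components))

    def pdf(self, ages) -> np.ndarray:
        """Density on an age grid.

        Point-mass components (sd = 0) carry weight but no finite density;
        they are excluded here and accounted for in :meth:`mean`.
        """
        t = np.asarray(ages, dtype=float)
        out = np.zeros_like(t)
        for _d, w, mu, sd in self.components:
            if sd > 0:
                out += w * norm.pdf(t, loc=mu, scale=sd)
        return out

    @property
    def point_masses(self) -> list[tuple[str, float, float]]:
        return [(d, w, mu) for d, w, mu, sd in self.components if sd == 0]


def onsets_from_profiles(profiles: Sequence[DiseaseProfile]) -> dict[str, tuple[float, float]]:
    """Collect (onset_mean, onset_sd) per disease; sd defaults to 0."""
    return {
        p.name: (float(p.onset_mean), float(p.onset_sd or 0.0))
        for p in profiles
        if p.onset_mean is not None
    }


def parameter_onset_density(
    matrix: PhenotypeMatrix, onsets: Onsets, parameter: str
) -> OnsetDensity:
    """Mixture over the diseases showing ``parameter`` with known onset.

    Component weight for a disease is proportional to the parameter's
    prevalence in that disease.
    """
    if parameter not in matrix.parameters:
        raise ValidationError(f"unknown parameter {parameter!r}")
    j = matrix.parameters.index(parameter)
    contrib = [
        (d, float(matrix.values[i, j]))
        for i, d in enumerate(matrix.diseases)
        if matrix.values[i, j] > 0 and d in onsets
    ]
    if not contrib:
        raise ValidationError(
            f"no disease with positive prevalence of {parameter!r} and a known onset"
        )
    total = sum(p for _d, p in contrib)
    components = [
        (d, p / total, float(onsets[d][0]), float(onsets[d][1])) for d, p in contrib
    ]
    return OnsetDensity(parameter=parameter, components=components)


def split_by_onset(
    matrix: PhenotypeMatrix, onsets: Onsets, cutoff: float = 20.0
) -> tuple[PhenotypeMatrix, PhenotypeMatrix]:
    """Split diseases into early (< cutoff) and late (>= cutoff) onset.

    Diseases without a known onset are excluded with a warning.
    """
    early, late, missing = [], [], []
    for d in matrix.diseases:
        if d not in onsets:
            missing.append(d)
        elif onsets[d][0] < cutoff:
            early.append(d)
        else:
            late.append(d)
    if missing:
        warnings.warn(
            f"{len(missing)} disease(s) without onset excluded from split: {missing}",
            stacklevel=2,
        )
    return matrix.subset_diseases(early), matrix.subset_diseases(late)


def early_late_correlation(
    matrix: PhenotypeMatrix, onsets: Onsets, cutoff: float = 20.0
) -> float:
    """Pearson correlation of the early- vs late-onset mean phenotype profiles.

    Both profiles are means over the full parameter union of ``matrix``
    (absent parameter = 0), so the statistic is symmetric in the two sides
    and invariant to parameter order.
    """
    early, late = split_by_onset(matrix, onsets, cutoff)
    if len(early.diseases) == 0 or len(late.diseases) == 0:
        raise ValidationError("early/late correlation requires both onset groups non-empty")
    em = early.values.mean(axis=0)
    lm = late.values.mean(axis=0)
    if np.ptp(em) == 0 or np.ptp(lm) == 0:
        raise UndefinedSimilarityError("early/late correlation undefined: zero variance")
    return float(pearsonr(em, lm).statistic)
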