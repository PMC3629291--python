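"""Synthetic phenotype databases with the statistical structure of a
reference-positive group sharing a high-prevalence core.

The generator emulates the structure that makes phenotype-overlap
classification work: the positive group (default 31 diseases) shares a
core of clinical parameters, each present at high prevalence (Beta(5, 2)
rescaled to percent), while the negative control group (default 25
diseases) is heterogeneous: each carries disease-private parameters no
other disease shows, plus core parameters at a configurable
``background_rate`` and low prevalence.  Positive diseases carry private
parameters too.  A handful of nonspecific *common* parameters
(fatigue-like findings any disease presents) is carried by every disease
at low prevalence; being group-agnostic they carry no class signal, but
they keep every disease weakly connected to every other, as in real
clinical data — without them the control group would be mutually
orthogonal and its dendrogram structure arbitrary.

Test profiles emulate diseases phenotypically akin to the database's
groups: each blends a few randomly chosen reference diseases of the
requested regime (parameter union, averaged prevalences) and jitters the
prevalences.  The true regime is returned out-of-band
(and written to a sidecar file by the CLI) so classifiers cannot read the
answer from the input.

``background_rate = 0`` makes the two groups disjoint on the core (the
only group-identifying structure) and the classification problem separable
by construction; ``core_size = 0`` removes that structure entirely,
leaving the groups exchangeable — a null database in which no method
should find a signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .phenodb import DiseaseProfile, StudyRecord

__all__ = ["SyntheticConfig", "SyntheticDatabase", "generate", "generate_studies"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic database.

    Defaults mirror a reference database of 31 positive and 25 negative
    diseases with a shared high-prevalence core in the positive group.
    """

    n_positive: int = 31
    n_negative: int = 25
    n_test: int = 6
    core_size: int = 20
    private_size: int = 5
    common_size: int = 8
    core_prevalence_shape: tuple[float, float] = (5.0, 2.0)
    private_prevalence_shape: tuple[float, float] = (2.0, 2.0)
    background_prevalence_shape: tuple[float, float] = (2.0, 5.0)
    common_prevalence_shape: tuple[float, float] = (4.0, 8.0)
    background_rate: float = 0.1
    test_sources: int = 3
    jitter_sd: float = 10.0
    onset_early_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("n_positive", "n_negative", "n_test", "core_size", "private_size",
                     "common_size"):
            if getattr(self, attr) < 0:
                raise ValidationError(f"{attr} must be >= 0")
        if self.n_positive + self.n_negative + self.n_test == 0:
            raise ValidationError("degenerate config: all disease counts are 0")
        if self.n_test > 0 and (self.n_positive == 0 or self.n_negative == 0):
            raise ValidationError("test profiles require both reference groups")
        if self.test_sources < 1:
            raise ValidationError("test_sources must be >= 1")
        for attr in ("background_rate", "onset_early_fraction"):
            if not 0.0 <= getattr(self, attr) <= 1.0:
                raise ValidationError(f"{attr} must be in [0, 1]")


@dataclass
class SyntheticDatabase:
    profiles: list[DiseaseProfile]
    test_truth: dict[str, str] = field(default_factory=dict)  # test name -> regime


def _beta_percent(rng: np.random.Generator, shape: tuple[float, float]) -> float:
    # floor at 0.01 % so a drawn parameter is always "present"
    return float(max(0.01, min(100.0, 100.0 * rng.beta(*shape))))


def _draw_onset(rng: np.random.Generator, early_fraction: float) -> tuple[float, float]:
    if rng.random() < early_fraction:
        mean = float(rng.uniform(0.5, 15.0))
    else:
        mean = float(rng.uniform(25.0, 65.0))
    return mean, float(rng.uniform(1.0, 8.0))


def generate(config: SyntheticConfig) -> SyntheticDatabase:
    """Generate a synthetic database; identical config gives identical output."""
    rng = np.random.default_rng(config.seed)
    core = [f"core_p{i + 1:02d}" for i in range(config.core_size)]
    common = [f"common_p{i + 1:02d}" for i in range(config.common_size)]

    def draw_common_and_private(name: str, prev: dict[str, float]) -> None:
        for p in common:
            prev[p] = _beta_percent(rng, config.common_prevalence_shape)
        for i in range(config.private_size):
            prev[f"{name}_priv{i + 1}"] = _beta_percent(rng, config.private_prevalence_shape)
        if not prev:  # a profile must carry at least one parameter
            prev[f"{name}_priv1"] = _beta_percent(rng, config.private_prevalence_shape)

    def positive_regime(name: str) -> dict[str, float]:
        prev = {p: _beta_percent(rng, config.core_prevalence_shape) for p in core}
        draw_common_and_private(name, prev)
        return prev

    def negative_regime(name: str) -> dict[str, float]:
        prev: dict[str, float] = {}
        for p in core:
            if rng.random() < config.background_rate:
                prev[p] = _beta_percent(rng, config.background_prevalence_shape)
        draw_common_and_private(name, prev)
        return prev

    def blended(sources: list[DiseaseProfile]) -> dict[str, float]:
        # union of the sources' parameters, prevalences averaged over the
        # sources carrying each one, then jittered: a disease phenotypically
        # akin to (but not identical with) the regime's database members
        pooled: dict[str, list[float]] = {}
        for s in sources:
            for p, v in s.prevalences.items():
                pooled.setdefault(p, []).append(v)
        return {
            p: float(np.clip(np.mean(vs) + rng.normal(0.0, config.jitter_sd), 0.01, 100.0))
            for p, vs in pooled.items()
        }

    def make(name: str, group: str, prevalences: dict[str, float]) -> DiseaseProfile:
        onset_mean, onset_sd = _draw_onset(rng, config.onset_early_fraction)
        return DiseaseProfile(
            name=name,
            group=group,
            prevalences=prevalences,
            n_patients=int(rng.integers(20, 500)),
            onset_mean=round(onset_mean, 3),
            onset_sd=round(onset_sd, 3),
        )

    profiles: list[DiseaseProfile] = []
    for i in range(config.n_positive):
        name = f"pos{i + 1:02d}"
        profiles.append(make(name, "positive", positive_regime(name)))
    for i in range(config.n_negative):
        name = f"neg{i + 1:02d}"
        profiles.append(make(name, "negative", negative_regime(name)))
    by_group = {
        "positive": profiles[: config.n_positive],
        "negative": profiles[config.n_positive :],
    }
    truth: dict[str, str] = {}
    for i in range(config.n_test):
        # alternate regimes so both kinds of test profile are always present
        regime = "positive" if i % 2 == 0 else "negative"
        pool = by_group[regime]
        k = min(config.test_sources, len(pool))
        sources = [pool[j] for j in sorted(rng.choice(len(pool), size=k, replace=False))]
        name = f"test{i + 1:02d}"
        profiles.append(make(name, "test", blended(sources)))
        truth[name] = regime
    return SyntheticDatabase(profiles=profiles, test_truth=truth)


def generate_studies(
    profile: DiseaseProfile, n_studies: int, seed: int
) -> list[StudyRecord]:
    """Split a disease's cohort into studies with binomially resampled prevalences.

    Patients are partitioned across studies (each study gets >= 1); each
    study's prevalence of a parameter is a binomial draw at the profile's
    true rate, so the patient-weighted merge of the studies is an unbiased
    estimate of the profile.
    """
    if profile.n_patients < 1:
        raise ValidationError(f"disease {profile.name!r} has no patients to partition")
    if not 1 <= n_studies <= profile.n_patients:
        raise ValidationError(
            f"n_studies must be in [1, {profile.n_patients}], got {n_studies}"
        )
    rng = np.random.default_rng(seed)
    counts = np.ones(n_studies, dtype=int)
    extra = rng.multinomial(profile.n_patients - n_studies, np.full(n_studies, 1 / n_studies))
    counts += extra
    if n_studies == 1:
        # single study reproduces the profile exactly
        return [
            StudyRecord(
                study_id=f"{profile.name}/study1",
                n_patients=profile.n_patients,
                prevalences=dict(profile.prevalences),
            )
        ]
    studies = []
    for s in range(n_studies):
        n = int(counts[s])
        prev = {
            p: 100.0 * rng.binomial(n, v / 100.0) / n for p, v in profile.prevalences.items()
        }
        studies.append(
            StudyRecord(study_id=f"{profile.name}/study{s + 1}", n_patients=n, prevalences=prev)
        )
    return studies
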