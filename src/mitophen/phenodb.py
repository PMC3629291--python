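"""Core phenotype-database model and I/O.

A disease is represented by its *symptom vector*: a map from clinical
parameter (a sign, symptom, laboratory or paraclinical finding) to the
prevalence of that parameter among the disease's reported patients, in
percent.  Diseases carry a group label — ``positive`` for the reference
group of interest (e.g. established mitochondrial diseases), ``negative``
for control diseases, ``test`` for diseases under investigation — and
optionally the mean and standard deviation of the age of onset in years.

Multiple source studies of the same disease are pooled by patient-weighted
averaging: the merged prevalence of a parameter is the prevalence among the
combined number of patients, a study that does not report the parameter
contributing zero cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

GROUPS = ("positive", "negative", "test")

__all__ = [
    "GROUPS",
    "StudyRecord",
    "DiseaseProfile",
    "PhenotypeMatrix",
    "GroupProfile",
    "merge_studies",
    "build_matrix",
    "group_profile",
    "top_parameters",
    "read_db",
    "write_db",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


def _normalize_parameters(prevalences: Mapping[str, float], owner: str) -> dict[str, float]:
    """Lower-case and trim parameter names; validate the percent range.

    Collisions after normalization ("Ataxia" vs "ataxia ") are rejected
    rather than silently merged.
    """
    out: dict[str, float] = {}
    for raw_name, value in prevalences.items():
        name = str(raw_name).strip().lower()
        if not name:
            raise ValidationError(f"{owner}: empty parameter name")
        value = float(value)
        if not np.isfinite(value) or not (0.0 <= value <= 100.0):
            raise ValidationError(
                f"{owner}: prevalence of {name!r} is {value}, outside [0, 100]"
            )
        if name in out:
            raise ValidationError(
                f"{owner}: parameter name collision after normalization: {name!r}"
            )
        out[name] = value
    return out


@dataclass(frozen=True)
class StudyRecord:
    """One source study of a disease: cohort size and reported prevalences."""

    study_id: str
    n_patients: int
    prevalences: Mapping[str, float]
    citation: str | None = None

    def __post_init__(self) -> None:
        if int(self.n_patients) < 1:
            raise ValidationError(
                f"study {self.study_id!r}: n_patients must be >= 1, got {self.n_patients}"
            )
        object.__setattr__(
            self, "prevalences", _normalize_parameters(self.prevalences, f"study {self.study_id!r}")
        )


@dataclass
class DiseaseProfile:
    """One disease: symptom vector, group label, cohort size, optional onset."""

    name: str
    group: str
    prevalences: dict[str, float]
    n_patients: int = 0
    onset_mean: float | None = None
    onset_sd: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"disease {self.name!r}: unknown group {self.group!r} (expected one of {GROUPS})"
            )
        if not self.prevalences:
            raise ValidationError(f"disease {self.name!r}: no clinical parameters")
        self.prevalences = _normalize_parameters(self.prevalences, f"disease {self.name!r}")
        if int(self.n_patients) < 0:
            raise ValidationError(f"disease {self.name!r}: negative n_patients")
        if self.onset_sd is not None and self.onset_mean is None:
            raise ValidationError(
                f"disease {self.name!r}: onset_sd given without onset_mean"
            )
        for attr in ("onset_mean", "onset_sd"):
            v = getattr(self, attr)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValidationError(f"disease {self.name!r}: {attr} must be >= 0 years")


@dataclass(frozen=True)
class GroupProfile:
    """Per-parameter mean prevalence across the diseases of one group."""

    group: str
    mean_prevalence: dict[str, float]
    n_diseases: int


@dataclass
class PhenotypeMatrix:
    """Dense diseases x parameters prevalence matrix.

    Columns span the union of parameters across all diseases; a parameter
    absent from a disease is stored as 0 %.  Row order follows the input
    database; column order is first-appearance order, so a database file
    always yields the same matrix (and hence the same clustering leaf
    order).
    """

    diseases: list[str]
    parameters: list[str]
    values: np.ndarray
    groups: list[str]
    _row_index: dict[str, int] = field(init=False, repr=False)
    _col_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.diseases), len(self.parameters)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.diseases)} diseases x {len(self.parameters)} parameters"
            )
        if len(self.groups) != len(self.diseases):
            raise ValidationError("one group label per disease required")
        self._row_index = {d: i for i, d in enumerate(self.diseases)}
        self._col_index = {p: j for j, p in enumerate(self.parameters)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, disease: str) -> np.ndarray:
        return self.values[self._row_index[disease]]

    def group_of(self, disease: str) -> str:
        return self.groups[self._row_index[disease]]

    def group_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.groups) == group)

    def subset_diseases(self, names: Sequence[str]) -> "PhenotypeMatrix":
        idx = [self._row_index[n] for n in names]
        return PhenotypeMatrix(
            diseases=list(names),
            parameters=list(self.parameters),
            values=self.values[idx].copy(),
            groups=[self.groups[i] for i in idx],
        )

    def subset_parameters(self, names: Sequence[str]) -> "PhenotypeMatrix":
        idx = [self._col_index[n] for n in names]
        return PhenotypeMatrix(
            diseases=list(self.diseases),
            parameters=list(names),
            values=self.values[:, idx].copy(),
            groups=list(self.groups),
        )

    def profile(self, disease: str) -> DiseaseProfile:
        """Reconstruct a profile from a row, dropping zero entries."""
        row = self.row(disease)
        prev = {p: row[j] for j, p in enumerate(self.parameters) if row[j] > 0}
        return DiseaseProfile(name=disease, group=self.group_of(disease), prevalences=prev)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.diseases, columns=self.parameters)


def merge_studies(
    studies: Sequence[StudyRecord], *, reporting_only: bool = False
) -> tuple[dict[str, float], int]:
    """Pool several studies into one prevalence map by patient weighting.

    The merged prevalence of parameter ``p`` is ``sum(n_i * p_i) / sum(n_i)``
    over all studies, a study not reporting ``p`` contributing prevalence 0
    for its patients.  With ``reporting_only=True`` the denominator for each
    parameter is restricted to the studies that report it.

    Returns the merged map and the total patient count.
    """
    if not studies:
        raise ValidationError("no studies")
    total_n = sum(s.n_patients for s in studies)
    params: list[str] = []
    seen = set()
    for s in studies:
        for p in s.prevalences:
            if p not in seen:
                seen.add(p)
                params.append(p)
    merged: dict[str, float] = {}
    for p in params:
        num = sum(s.n_patients * s.prevalences.get(p, 0.0) for s in studies)
        if reporting_only:
            den = sum(s.n_patients for s in studies if p in s.prevalences)
        else:
            den = total_n
        merged[p] = num / den
    return merged, total_n


def build_matrix(profiles: Sequence[DiseaseProfile]) -> PhenotypeMatrix:
    """Materialize profiles into a dense matrix over the parameter union."""
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate disease names: {dupes}")
    parameters: list[str] = []
    seen = set()
    for prof in profiles:
        for p in prof.prevalences:
            if p not in seen:
                seen.add(p)
                parameters.append(p)
    values = np.zeros((len(profiles), len(parameters)))
    col = {p: j for j, p in enumerate(parameters)}
    for i, prof in enumerate(profiles):
        for p, v in prof.prevalences.items():
            values[i, col[p]] = v
    return PhenotypeMatrix(
        diseases=names,
        parameters=parameters,
        values=values,
        groups=[p.group for p in profiles],
    )


def group_profile(matrix: PhenotypeMatrix, group: str) -> GroupProfile:
    """Average the occurrence of each parameter across one group's diseases.

    A disease not carrying a parameter counts as 0 %, so the mean is over
    all diseases of the group, not only the reporting ones.
    """
    idx = matrix.group_indices(group)
    if idx.size == 0:
        raise ValidationError(f"empty group {group!r}")
    means = matrix.values[idx].mean(axis=0)
    return GroupProfile(
        group=group,
        mean_prevalence={p: float(means[j]) for j, p in enumerate(matrix.parameters)},
        n_diseases=int(idx.size),
    )


def top_parameters(profile: GroupProfile, n: int) -> list[tuple[str, float]]:
    """The N most prevalent parameters of a group profile.

    Sorted by mean prevalence descending; ties broken alphabetically.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    ranked = sorted(profile.mean_prevalence.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


# ---------------------------------------------------------------------------
# I/O: JSON database and TSV matrix


def _profile_from_json(record: dict, pos: int) -> DiseaseProfile:
    if not isinstance(record, dict):
        raise ValidationError(f"disease record #{pos} is not an object")
    name = record.get("name")
    if not name:
        raise ValidationError(f"disease record #{pos}: missing 'name'")
    for key in ("group",):
        if key not in record:
            raise ValidationError(f"disease {name!r}: missing {key!r}")
    prevalences = record.get("parameters")
    studies_json = record.get("studies")
    n_patients = record.get("n_patients", 0)
    studies = None
    if studies_json:
        studies = [
            StudyRecord(
                study_id=str(s.get("study_id", f"{name}/{k}")),
                n_patients=int(s["n_patients"]),
                prevalences=s["parameters"],
                citation=s.get("citation"),
            )
            for k, s in enumerate(studies_json)
        ]
    if prevalences is None:
        if not studies:
            raise ValidationError(f"disease {name!r}: neither 'parameters' nor 'studies'")
        prevalences, n_patients = merge_studies(studies)
    try:
        return DiseaseProfile(
            name=str(name),
            group=record["group"],
            prevalences=prevalences,
            n_patients=int(n_patients),
            onset_mean=record.get("onset_mean"),
            onset_sd=record.get("onset_sd"),
        )
    except ValidationError:
        raise
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"disease {name!r}: {exc}") from exc


def read_db(path: str | Path) -> list[DiseaseProfile]:
    """Read a JSON phenotype database.

    Format: ``{"diseases": [{"name", "group", "n_patients", "onset_mean",
    "onset_sd", "parameters": {param: percent}, "studies": [...]}, ...]}``.
    ``parameters`` may be omitted when ``studies`` are given, in which case
    the studies are merged by patient weighting on load.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(doc, dict) or "diseases" not in doc:
        raise ValidationError(f"{path}: expected an object with a 'diseases' list")
    profiles = [_profile_from_json(rec, i) for i, rec in enumerate(doc["diseases"])]
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValidationError(f"{path}: duplicate disease names")
    return profiles


def write_db(profiles: Iterable[DiseaseProfile], path: str | Path) -> None:
    """Write profiles as a JSON database (round-trips bit-exactly)."""
    records = []
    for p in profiles:
        rec: dict = {
            "name": p.name,
            "group": p.group,
            "n_patients": p.n_patients,
            "parameters": p.prevalences,
        }
        if p.onset_mean is not None:
            rec["onset_mean"] = p.onset_mean
        if p.onset_sd is not None:
            rec["onset_sd"] = p.onset_sd
        records.append(rec)
    Path(path).write_text(json.dumps({"diseases": records}, indent=1) + "\n")


def read_matrix_tsv(path: str | Path) -> PhenotypeMatrix:
    """Read a TSV matrix: columns ``disease``, ``group``, then parameters."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3 or list(df.columns[:2]) != ["disease", "group"]:
        raise ValidationError(f"{path}: expected columns 'disease', 'group', parameters...")
    values = df.iloc[:, 2:].to_numpy(dtype=float)
    diseases = df["disease"].tolist()
    groups = df["group"].tolist()
    for g, d in zip(groups, diseases):
        if g not in GROUPS:
            raise ValidationError(f"{path}: disease {d!r}: unknown group {g!r}")
    if np.any(values < 0) or np.any(values > 100):
        i, j = np.argwhere((values < 0) | (values > 100))[0]
        raise ValidationError(
            f"{path}: disease {diseases[i]!r}: prevalence {values[i, j]} outside [0, 100]"
        )
    parameters = [str(c).strip().lower() for c in df.columns[2:]]
    if len(set(parameters)) != len(parameters):
        raise ValidationError(f"{path}: parameter name collision after normalization")
    return PhenotypeMatrix(diseases=diseases, parameters=parameters, values=values, groups=groups)


def write_matrix_tsv(matrix: PhenotypeMatrix, path: str | Path) -> None:
    df = matrix.to_dataframe().round(6)
    df.insert(0, "group", matrix.groups)
    df.insert(0, "disease", matrix.diseases)
    df.to_csv(path, sep="\t", index=False)
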