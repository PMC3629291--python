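"""Phenotype barcode: shared-parameter bars between a test disease and a database.

One bar per (database disease, shared parameter) pair.  The bar's tint is
the prevalence of the parameter in the test disease multiplied by its
prevalence in the database disease, normalized to [0, 1].  Summed per group,
the tints say at a glance which reference group the test disease resembles:
a barcode dominated by positive-group bars is "more red", one dominated by
controls "more green".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

from .errors import ValidationError
from .phenodb import GROUPS, DiseaseProfile, PhenotypeMatrix

__all__ = ["Bar", "Barcode", "barcode", "barcode_summary", "write_barcode_tsv"]

_GROUP_RANK = {g: i for i, g in enumerate(GROUPS)}  # positive < negative < test


class Bar(NamedTuple):
    disease: str
    group: str
    parameter: str
    tint: float


@dataclass
class Barcode:
    test_disease: str
    bars: list[Bar]


def barcode(test: DiseaseProfile, matrix: PhenotypeMatrix) -> Barcode:
    """Bars for every database parameter shared with the test disease.

    tint = p_test * p_db / 10000.  Bars are ordered by database group
    (positive, then negative, then test), disease name, then tint
    descending (ties by parameter name), so output is deterministic.
    """
    if len(matrix.diseases) == 0:
        raise ValidationError("empty database")
    bars: list[Bar] = []
    col = {p: j for j, p in enumerate(matrix.parameters)}
    for name, group in zip(matrix.diseases, matrix.groups):
        row = matrix.row(name)
        for param, p_test in test.prevalences.items():
            j = col.get(param)
            if j is None or p_test <= 0 or row[j] <= 0:
                continue
            bars.append(Bar(name, group, param, float(p_test * row[j] / 10000.0)))
    bars.sort(key=lambda b: (_GROUP_RANK[b.group], b.disease, -b.tint, b.parameter))
    return Barcode(test_disease=test.name, bars=bars)


def barcode_summary(bc: Barcode) -> tuple[float, float]:
    """Total tint mass from the positive and the negative reference group."""
    pos = sum(b.tint for b in bc.bars if b.group == "positive")
    neg = sum(b.tint for b in bc.bars if b.group == "negative")
    return float(pos), float(neg)


def write_barcode_tsv(bc: Barcode, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["disease", "group", "parameter", "tint"])
        for b in bc.bars:
            w.writerow([b.disease, b.group, b.parameter, f"{b.tint:.9g}"])
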