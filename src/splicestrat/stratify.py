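"""Patient stratification by isoform expression, race, and sample type.

Two grouping rules are used downstream of isoform quantification:

* ``mean_split`` -- for the continuously expressed full-length isoform
  (p85alpha): the threshold is the arithmetic mean of the per-cancer tumor
  log expression values; a sample is ``high`` iff its value is strictly
  above the mean, ``low`` otherwise (ties at the mean go to ``low``).
* ``zero_nonzero`` -- for the alternative-first-exon isoform (p55alpha),
  whose junction counts have a point mass at zero: ``low`` iff the raw
  discriminating-junction count is exactly 0, ``high`` otherwise.

Cohort construction partitions samples by (cancer type, race group,
tumor/normal).  Race strings are mapped case-insensitively onto
African American (AA) and European American (EA); anything else is kept
under ``NA-other`` and flagged as excluded from between-group tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, JoinError, UsageError

__all__ = [
    "GroupLabel",
    "CohortKey",
    "split_by_mean",
    "split_zero_nonzero",
    "build_cohorts",
    "DEFAULT_RACE_SYNONYMS",
]

#: Case-insensitive mapping of clinical race strings onto analysis groups.
DEFAULT_RACE_SYNONYMS: dict[str, str] = {
    "black or african american": "AA",
    "african american": "AA",
    "aa": "AA",
    "white": "EA",
    "european american": "EA",
    "ea": "EA",
}


@dataclass(frozen=True)
class GroupLabel:
    barcode: str
    rule: str  # mean_split | zero_nonzero
    label: str  # low | high
    threshold_used: float


@dataclass(frozen=True)
class CohortKey:
    cancer: str
    race: str  # AA | EA | NA-other
    sample_type: str  # tumor | normal


def _barcodes(values, barcodes) -> list[str]:
    if barcodes is not None:
        barcodes = list(barcodes)
        if len(barcodes) != len(values):
            raise UsageError("barcodes length must match values length")
        return barcodes
    if isinstance(values, pd.Series):
        return [str(b) for b in values.index]
    return [str(i) for i in range(len(values))]


def split_by_mean(
    values: Sequence[float] | pd.Series, barcodes: Sequence[str] | None = None
) -> list[GroupLabel]:
    """Label each sample ``high`` iff its value exceeds the group mean.

    Intended for one cancer type's tumor samples on the log scale.  All
    input values equal (threshold uninformative) yields all-``low`` with a
    warning.
    """
    names = _barcodes(values, barcodes)
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise UsageError(f"mean split requires >= 2 samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise DataError("non-finite expression value in mean split input")
    threshold = float(arr.mean())
    if np.ptp(arr) == 0:
        warnings.warn(
            "all expression values identical; mean split is degenerate "
            "(all samples labeled low)",
            UserWarning,
            stacklevel=2,
        )
    return [
        GroupLabel(b, "mean_split", "high" if v > threshold else "low", threshold)
        for b, v in zip(names, arr)
    ]


def split_zero_nonzero(
    raw_counts: Sequence[int] | pd.Series, barcodes: Sequence[str] | None = None
) -> list[GroupLabel]:
    """Label ``low`` iff the raw count is exactly zero, ``high`` otherwise."""
    names = _barcodes(raw_counts, barcodes)
    arr = np.asarray(raw_counts)
    if arr.size and arr.min() < 0:
        raise DataError("raw counts must be non-negative")
    return [
        GroupLabel(b, "zero_nonzero", "low" if c == 0 else "high", 0.0)
        for b, c in zip(names, arr)
    ]


def map_race(race: object, synonyms: Mapping[str, str] | None = None) -> str:
    """Collapse a free-text race string onto {AA, EA, NA-other}."""
    table = DEFAULT_RACE_SYNONYMS if synonyms is None else synonyms
    if race is None or (isinstance(race, float) and math.isnan(race)):
        return "NA-other"
    return table.get(str(race).strip().lower(), "NA-other")


def build_cohorts(
    metadata: pd.DataFrame,
    labels: Iterable[GroupLabel] | None = None,
    race_synonyms: Mapping[str, str] | None = None,
    barcode_col: str = "bcr_patient_barcode",
    cancer_col: str = "type",
    sample_type_col: str = "sample_type",
    race_col: str = "race",
) -> tuple[dict[CohortKey, list[str]], pd.DataFrame]:
    """Partition samples by (cancer, race group, tumor/normal).

    Returns the cohort mapping plus a per-sample assignment table with
    columns ``barcode, cancer, race_group, sample_type, label,
    excluded_from_tests``.  Normal samples carry no low/high label; samples
    whose race maps outside {AA, EA} are retained under ``NA-other`` with
    the exclusion flag set.  Every labeled barcode must exist in
    ``metadata``.
    """
    meta = metadata.set_index(metadata[barcode_col].astype(str))
    label_map: dict[str, str] = {}
    if labels is not None:
        label_map = {gl.barcode: gl.label for gl in labels}
        missing = sorted(set(label_map) - set(meta.index))
        if missing:
            raise JoinError(
                f"labeled barcodes absent from metadata: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
    rows = []
    cohorts: dict[CohortKey, list[str]] = {}
    for barcode, row in meta.iterrows():
        race_group = map_race(row[race_col], race_synonyms)
        stype = str(row[sample_type_col]).strip().lower()
        stype = "normal" if stype.startswith("normal") else "tumor"
        label = label_map.get(barcode) if stype == "tumor" else None
        key = CohortKey(str(row[cancer_col]), race_group, stype)
        cohorts.setdefault(key, []).append(str(barcode))
        rows.append(
            {
                "barcode": str(barcode),
                "cancer": key.cancer,
                "race_group": race_group,
                "sample_type": stype,
                "label": label,
                "excluded_from_tests": race_group == "NA-other",
            }
        )
    return cohorts, pd.DataFrame(rows)
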