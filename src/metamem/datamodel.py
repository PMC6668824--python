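"""Canonical participant data model, CSV ingestion, derived scoring and normalization.

A cohort is a collection of :class:`ParticipantRecord` objects, one per
subject, each holding an age group (young/old), a stimulus condition
(words/names/nonwords) and a 9-measure x 2-test-type grid of scores:
recognition performance (hit rate minus false-alarm rate), memory
self-efficacy, postdiction, postdiction accuracy, perceived strategy
success, and ratings of difficulty, effort, fatigue and stamina.

The canonical column order is test-type major: the nine item-test columns
first, then the nine associate-test columns, with measures ordered
performance, self-efficacy, postdiction, postdiction accuracy, strategy,
difficulty, effort, fatigue, stamina.  All matrix-producing functions in
the package index variables in this order, which makes network weight
indexing and feature-subset (ablation) selection reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MEASURES",
    "TEST_TYPES",
    "AGE_GROUPS",
    "STIMULUS_CONDITIONS",
    "CANONICAL_COLUMNS",
    "MEASURE_RANGES",
    "CohortSchemaError",
    "CohortValidationError",
    "ParticipantRecord",
    "FeatureMatrix",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "feature_matrix",
    "age_targets",
    "recognition_score",
    "postdiction_accuracy",
    "mseq_score",
    "zscore_normalize",
    "select_features",
]

#: Measure names in table order (performance first, then the metacognitive scales).
MEASURES: tuple[str, ...] = (
    "recognition",
    "mseq",
    "postdiction",
    "postdiction_accuracy",
    "strategy",
    "difficulty",
    "effort",
    "fatigue",
    "stamina",
)

TEST_TYPES: tuple[str, ...] = ("item", "assoc")
AGE_GROUPS: tuple[str, ...] = ("young", "old")
STIMULUS_CONDITIONS: tuple[str, ...] = ("words", "names", "nonwords")

#: Legal (inclusive) range of each measure on its raw scale.
MEASURE_RANGES: dict[str, tuple[float, float]] = {
    "recognition": (-1.0, 1.0),
    "mseq": (0.0, 100.0),
    "postdiction": (0.0, 100.0),
    "postdiction_accuracy": (-1.0, 1.0),
    "strategy": (0.0, 100.0),
    "difficulty": (1.0, 5.0),
    "effort": (1.0, 5.0),
    "fatigue": (1.0, 5.0),
    "stamina": (1.0, 5.0),
}

#: The 18 canonical feature columns: 9 item-test columns, then 9 associate-test.
CANONICAL_COLUMNS: tuple[str, ...] = tuple(
    f"{measure}_{test}" for test in TEST_TYPES for measure in MEASURES
)

_META_COLUMNS = ("id", "age_group", "stimulus_condition")


class CohortSchemaError(ValueError):
    """A cohort file is structurally unusable (missing column, empty file)."""


class CohortValidationError(ValueError):
    """A cohort value violates its declared range or enumeration."""


def _measure_of(column: str) -> str:
    measure, _, test = column.rpartition("_")
    if measure not in MEASURES or test not in TEST_TYPES:
        raise KeyError(f"not a canonical column: {column!r}")
    return measure


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject: demographics plus the 9 x 2 measure grid.

    ``measures`` maps canonical column names (``recognition_item`` ...
    ``stamina_assoc``) to raw-scale values.  Construction validates the
    age group, the stimulus condition, the presence of all 18 measures
    and every value's range.
    """

    id: str
    age_group: str
    stimulus_condition: str
    measures: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise CohortValidationError("participant id must be non-empty")
        if self.age_group not in AGE_GROUPS:
            raise CohortValidationError(
                f"participant {self.id}: unknown age_group {self.age_group!r}"
            )
        if self.stimulus_condition not in STIMULUS_CONDITIONS:
            raise CohortValidationError(
                f"participant {self.id}: unknown stimulus_condition "
                f"{self.stimulus_condition!r}"
            )
        missing = [c for c in CANONICAL_COLUMNS if c not in self.measures]
        if missing:
            raise CohortValidationError(
                f"participant {self.id}: missing measures {missing}"
            )
        for column in CANONICAL_COLUMNS:
            value = float(self.measures[column])
            lo, hi = MEASURE_RANGES[_measure_of(column)]
            if not math.isfinite(value) or not (lo <= value <= hi):
                raise CohortValidationError(
                    f"participant {self.id}: {column} = {value} outside [{lo}, {hi}]"
                )

    def values(self) -> np.ndarray:
        """The 18 measures in canonical column order."""
        return np.array([self.measures[c] for c in CANONICAL_COLUMNS], dtype=float)


@dataclass(frozen=True)
class FeatureMatrix:
    """An n x p feature matrix with canonical column labels and provenance.

    ``scale`` records whether values are raw or z-scored; downstream
    stages that require standardized input check it.
    """

    values: np.ndarray
    column_labels: tuple[str, ...]
    row_ids: tuple[str, ...]
    scale: str = "raw"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "column_labels", tuple(self.column_labels))
        object.__setattr__(self, "row_ids", tuple(self.row_ids))
        if values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if values.shape != (len(self.row_ids), len(self.column_labels)):
            raise ValueError(
                f"shape {values.shape} inconsistent with {len(self.row_ids)} rows "
                f"and {len(self.column_labels)} labels"
            )
        if self.scale not in ("raw", "zscored"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Derived scoring
# ---------------------------------------------------------------------------

def recognition_score(hits: int, false_alarms: int, n_old: int, n_new: int) -> float:
    """Recognition memory score: hit rate minus false-alarm rate.

    ``hits`` is the count of "old" responses to studied items (or intact
    pairs) out of ``n_old`` targets; ``false_alarms`` the count of "old"
    responses to new items (or recombined pairs) out of ``n_new`` lures.
    The result lies in [-1, 1].
    """
    if n_old <= 0 or n_new <= 0:
        raise ValueError("n_old and n_new must be positive")
    if not (0 <= hits <= n_old):
        raise ValueError(f"hits = {hits} outside [0, {n_old}]")
    if not (0 <= false_alarms <= n_new):
        raise ValueError(f"false_alarms = {false_alarms} outside [0, {n_new}]")
    return hits / n_old - false_alarms / n_new


def postdiction_accuracy(postdiction: float, recognition: float) -> float:
    """Postdiction rating minus proportion correct, as a proportion difference.

    ``postdiction`` is the participant's after-test estimate of how much
    they remembered (0-100).  For an equal old/new (intact/recombined)
    test, proportion correct equals ``(1 + recognition_score) / 2``
    because (hits + correct rejections) / total = (n + hits - FA) / 2n.
    Negative values indicate underestimation of one's own performance,
    positive values overestimation; zero is perfect calibration.
    """
    if not (0.0 <= postdiction <= 100.0):
        raise ValueError(f"postdiction = {postdiction} outside [0, 100]")
    if not (-1.0 <= recognition <= 1.0):
        raise ValueError(f"recognition = {recognition} outside [-1, 1]")
    return postdiction / 100.0 - (1.0 + recognition) / 2.0


_VALID_CONFIDENCES = frozenset(range(10, 101, 10))


def mseq_score(responses: Sequence[tuple[bool, float | None]]) -> float:
    """Memory self-efficacy score from graded yes/no + confidence responses.

    The questionnaire presents performance levels of increasing difficulty
    (8 levels on the item form, 4 on the associate form).  Each endorsed
    ("yes") level carries a confidence rating in {10, 20, ..., 100};
    unendorsed levels score zero.  The summary score is the mean over all
    levels, on a 0-100 scale.
    """
    if len(responses) not in (4, 8):
        raise ValueError(
            f"questionnaire has {len(responses)} levels; expected 8 (item) or 4 (associate)"
        )
    total = 0.0
    for i, (endorsed, confidence) in enumerate(responses):
        if endorsed:
            if confidence is None:
                raise ValueError(f"level {i + 1}: endorsed without a confidence rating")
            if confidence not in _VALID_CONFIDENCES:
                raise ValueError(
                    f"level {i + 1}: confidence {confidence} not in 10..100 by 10"
                )
            total += confidence
    return total / len(responses)


# ---------------------------------------------------------------------------
# Matrix construction and transforms
# ---------------------------------------------------------------------------

def cohort_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Wide DataFrame: id, age_group, stimulus_condition, 18 measure columns."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "id": rec.id,
            "age_group": rec.age_group,
            "stimulus_condition": rec.stimulus_condition,
        }
        row.update({c: rec.measures[c] for c in CANONICAL_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_META_COLUMNS) + list(CANONICAL_COLUMNS))


def feature_matrix(records: Sequence[ParticipantRecord]) -> FeatureMatrix:
    """Raw 18-column :class:`FeatureMatrix` in canonical order."""
    values = np.array([rec.values() for rec in records], dtype=float)
    if values.size == 0:
        values = values.reshape(0, len(CANONICAL_COLUMNS))
    return FeatureMatrix(
        values=values,
        column_labels=CANONICAL_COLUMNS,
        row_ids=tuple(rec.id for rec in records),
        scale="raw",
    )


def age_targets(records: Sequence[ParticipantRecord]) -> np.ndarray:
    """Bipolar classification targets: -1 for young, +1 for old."""
    return np.array([1.0 if r.age_group == "old" else -1.0 for r in records])


def zscore_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Standardize each column to mean 0, sample SD 1 (n-1 denominator).

    Raises if any column is constant: a zero-variance measure cannot serve
    as a network input unit.  Applying the transform to an already
    z-scored matrix is a no-op up to floating point.
    """
    if matrix.n < 2:
        raise ValueError("z-scoring requires at least 2 rows")
    values = matrix.values
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    constant = np.flatnonzero(sds == 0.0)
    if constant.size:
        names = [matrix.column_labels[j] for j in constant]
        raise ValueError(f"constant column(s) cannot be z-scored: {names}")
    return FeatureMatrix(
        values=(values - means) / sds,
        column_labels=matrix.column_labels,
        row_ids=matrix.row_ids,
        scale="zscored",
    )


_SUBSETS = {
    "all": TEST_TYPES,
    "item": ("item",),
    "associate": ("assoc",),
}


def select_features(matrix: FeatureMatrix, subset: str) -> FeatureMatrix:
    """Select the full 18-column grid or the 9-column item/associate half.

    ``subset`` is one of ``"all"``, ``"item"``, ``"associate"``.  Column
    order within the retained set is preserved, so the item and associate
    subsets partition the canonical 18 columns.
    """
    if subset not in _SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {sorted(_SUBSETS)}")
    if matrix.column_labels != CANONICAL_COLUMNS:
        raise ValueError("select_features requires the 18 canonical columns")
    keep_tests = _SUBSETS[subset]
    idx = [
        j
        for j, label in enumerate(matrix.column_labels)
        if label.rpartition("_")[2] in keep_tests
    ]
    return FeatureMatrix(
        values=matrix.values[:, idx],
        column_labels=tuple(matrix.column_labels[j] for j in idx),
        row_ids=matrix.row_ids,
        scale=matrix.scale,
    )


# ---------------------------------------------------------------------------
# CSV ingestion / emission
# ---------------------------------------------------------------------------

def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    layout: str = "wide",
) -> list[ParticipantRecord]:
    """Read a cohort CSV into validated records.

    ``layout="wide"`` expects one row per participant with columns
    ``id, age_group, stimulus_condition`` and the 18 canonical measure
    columns.  ``layout="long"`` expects tidy rows
    ``id, age_group, stimulus_condition, test_type, measure, value``.
    ``column_map`` maps canonical names to the file's actual headers when
    they differ (e.g. ``{"recognition_item": "HR_minus_FAR_item"}``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, dtype={0: str})
    except pd.errors.EmptyDataError as exc:
        raise CohortSchemaError(f"{path}: empty cohort file") from exc
    if frame.empty:
        raise CohortSchemaError(f"{path}: cohort file has a header but no rows")

    if column_map:
        rename = {actual: canonical for canonical, actual in column_map.items()}
        frame = frame.rename(columns=rename)

    if layout == "long":
        required = {"id", "age_group", "stimulus_condition", "test_type", "measure", "value"}
        missing = sorted(required - set(frame.columns))
        if missing:
            raise CohortSchemaError(f"{path}: long layout missing column(s) {missing}")
        frame = frame.assign(column=frame["measure"] + "_" + frame["test_type"])
        frame = frame.pivot(
            index=["id", "age_group", "stimulus_condition"], columns="column", values="value"
        ).reset_index()
    elif layout != "wide":
        raise ValueError(f"unknown layout {layout!r}")

    missing = [c for c in (*_META_COLUMNS, *CANONICAL_COLUMNS) if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing required column(s) {missing}")

    records = []
    for _, row in frame.iterrows():
        records.append(
            ParticipantRecord(
                id=str(row["id"]),
                age_group=str(row["age_group"]),
                stimulus_condition=str(row["stimulus_condition"]),
                measures={c: float(row[c]) for c in CANONICAL_COLUMNS},
            )
        )
    return records


def write_cohort(
    records: Sequence[ParticipantRecord],
    path: str | Path,
    float_format: str = "%.10g",
) -> None:
    """Write a wide-layout cohort CSV that round-trips through :func:`read_cohort`."""
    cohort_to_frame(records).to_csv(path, index=False, float_format=float_format)
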