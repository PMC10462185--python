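"""Domain types and I/O for two-group longitudinal tumor-volume studies.

The central container is :class:`StudyTable`, a validated long-format table
with one row per animal x time point.  From it, :func:`extract_pair` builds
the per-time-point paired vectors (volume at the previous observed time,
volume at the current time) that the homologous test consumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, PairExtractionError, StudyValidationError

#: canonical column names of the long format
COLUMNS = ("animal_id", "group", "time", "volume")


@dataclass
class ValidationReport:
    """Errors and warnings accumulated while reading/validating a study.

    ``errors`` empty means the study is usable; warnings record recoverable
    issues such as rows dropped for missing values.
    """

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class StudyTable:
    """Long-format two-group longitudinal study.

    Attributes
    ----------
    data : pandas.DataFrame
        Columns ``animal_id`` (str), ``group`` (int, 0/1), ``time`` (float),
        ``volume`` (float).  One row per animal x time point.
    group_labels : dict
        Maps the 0/1 treatment indicator to the display label seen on input.
    volume_scale : str
        ``"raw"`` (mm^3) or ``"log"`` (natural-log mm^3).
    report : ValidationReport
        Warnings collected while building the table.
    """

    data: pd.DataFrame
    group_labels: dict[int, str]
    volume_scale: str = "raw"
    report: ValidationReport = field(default_factory=ValidationReport)

    @property
    def times(self) -> np.ndarray:
        """Sorted distinct observation times."""
        return np.sort(self.data["time"].unique())

    def group_size(self, g: int) -> int:
        return self.data.loc[self.data["group"] == g, "animal_id"].nunique()

    def animals(self, g: int | None = None) -> list[str]:
        df = self.data if g is None else self.data[self.data["group"] == g]
        return sorted(df["animal_id"].unique())


@dataclass
class TimepointPairData:
    """Complete-case paired volumes at two adjacent observed time points.

    For each group g the vectors ``y_prev_g`` / ``y_curr_g`` hold, in stable
    animal-id order, the volumes of the animals measured at *both* times.
    ``n0 + n1`` is the sample size n entering the n-4 degrees of freedom.
    """

    time_prev: float
    time_curr: float
    y_prev_0: np.ndarray
    y_curr_0: np.ndarray
    y_prev_1: np.ndarray
    y_curr_1: np.ndarray
    group_labels: dict[int, str] = field(default_factory=lambda: {0: "0", 1: "1"})
    dropped: dict[int, int] = field(default_factory=lambda: {0: 0, 1: 0})

    def __post_init__(self):
        self.y_prev_0 = np.asarray(self.y_prev_0, dtype=float)
        self.y_curr_0 = np.asarray(self.y_curr_0, dtype=float)
        self.y_prev_1 = np.asarray(self.y_prev_1, dtype=float)
        self.y_curr_1 = np.asarray(self.y_curr_1, dtype=float)
        if self.y_prev_0.shape != self.y_curr_0.shape:
            raise StudyValidationError("group-0 pair vectors differ in length")
        if self.y_prev_1.shape != self.y_curr_1.shape:
            raise StudyValidationError("group-1 pair vectors differ in length")

    @property
    def n0(self) -> int:
        return self.y_curr_0.size

    @property
    def n1(self) -> int:
        return self.y_curr_1.size

    @property
    def n(self) -> int:
        return self.n0 + self.n1


def _resolve_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename user columns to the canonical names, erroring on absences."""
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    return df[list(COLUMNS)].copy()


def read_long_table(
    source: str | Path | io.TextIOBase,
    column_map: Mapping[str, str] | None = None,
    group_map: Mapping[str, int] | None = None,
    log_transform: bool = False,
) -> StudyTable:
    """Read a long-format CSV into a validated :class:`StudyTable`.

    Parameters
    ----------
    source : path or open text handle
        CSV with a header row; columns resolvable to ``animal_id``,
        ``group``, ``time``, ``volume``.
    column_map : mapping, optional
        Canonical name -> actual column name in the file.
    group_map : mapping, optional
        Display label -> 0/1 indicator.  By default the first-seen label
        becomes group 0 (labels "0"/"1" keep their numeric meaning).
    log_transform : bool
        If true, volumes are natural-log transformed on read and the table
        is marked ``volume_scale="log"``.

    Raises
    ------
    FormatError
        Missing columns or unparseable file.
    StudyValidationError
        More than two group labels, duplicated measurements, an animal in
        two groups, or fewer than two usable time points.
    """
    try:
        raw = pd.read_csv(source, dtype=str, skipinitialspace=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"could not parse CSV: {exc}") from exc
    raw = _resolve_columns(raw, column_map)
    report = ValidationReport()

    # parse numerics row-by-row so errors and NA drops carry row numbers
    time = pd.to_numeric(raw["time"], errors="coerce")
    volume = pd.to_numeric(raw["volume"], errors="coerce")
    bad_time = time.isna() & raw["time"].notna() & ~raw["time"].str.strip().str.upper().isin(["NA", "NAN", ""])
    if bad_time.any():
        row = int(bad_time.idxmax()) + 2  # header + 1-based
        raise FormatError(f"non-numeric time {raw['time'][bad_time.idxmax()]!r} at row {row}")
    incomplete = time.isna() | volume.isna() | raw["animal_id"].isna() | raw["group"].isna()
    if incomplete.any():
        rows = [int(i) + 2 for i in raw.index[incomplete]]
        report.warnings.append(
            f"dropped {incomplete.sum()} row(s) with missing/non-numeric values (rows {rows})"
        )
    df = pd.DataFrame(
        {
            "animal_id": raw["animal_id"].astype(str),
            "group_label": raw["group"].astype(str).str.strip(),
            "time": time,
            "volume": volume,
        }
    )[~incomplete.values].reset_index(drop=True)

    labels = list(dict.fromkeys(df["group_label"]))  # first-seen order
    if len(labels) > 2:
        raise StudyValidationError(f"expected at most two group labels, found: {', '.join(labels)}")
    if group_map is not None:
        unknown = [l for l in labels if l not in group_map]
        if unknown:
            raise StudyValidationError(f"group_map missing label(s): {', '.join(unknown)}")
        mapping = {l: int(group_map[l]) for l in labels}
    elif set(labels) <= {"0", "1"}:
        mapping = {l: int(l) for l in labels}
    else:
        mapping = {l: i for i, l in enumerate(labels)}
    df["group"] = df["group_label"].map(mapping).astype(int)
    group_labels = {v: k for k, v in mapping.items()}

    if log_transform:
        if (df["volume"] <= 0).any():
            raise StudyValidationError("log transform requested but nonpositive volumes present")
        df["volume"] = np.log(df["volume"])

    study = StudyTable(
        data=df[list(COLUMNS)],
        group_labels=group_labels,
        volume_scale="log" if log_transform else "raw",
        report=report,
    )
    validate_study(study, report)
    if not report.ok:
        raise StudyValidationError("; ".join(report.errors))
    return study


def validate_study(study: StudyTable, report: ValidationReport | None = None) -> ValidationReport:
    """Check the StudyTable invariants, collecting messages in a report."""
    report = report if report is not None else ValidationReport()
    df = study.data
    dup = df.duplicated(subset=["animal_id", "time"])
    if dup.any():
        pairs = df.loc[dup, ["animal_id", "time"]].itertuples(index=False)
        report.errors.append(
            "duplicate (animal_id, time) measurements: "
            + ", ".join(f"({a}, {t:g})" for a, t in pairs)
        )
    multi = df.groupby("animal_id")["group"].nunique()
    crossed = multi[multi > 1].index.tolist()
    if crossed:
        report.errors.append(f"animal(s) assigned to both groups: {', '.join(map(str, crossed))}")
    if df["time"].nunique() < 2:
        report.errors.append("study must contain at least two distinct time points")
    for g in (0, 1):
        if (df["group"] == g).sum() == 0:
            report.errors.append(f"group {g} ({study.group_labels.get(g, g)}) has no observations")
    if (df["volume"] < 0).any() and study.volume_scale == "raw":
        report.warnings.append("negative raw volumes present")
    return report


def write_long_table(study: StudyTable, path: str | Path | io.TextIOBase) -> None:
    """Write the study back to the canonical long CSV dialect.

    Group values are written as their display labels so a round trip through
    :func:`read_long_table` reproduces the original encoding.
    """
    out = study.data.copy()
    out["group"] = out["group"].map(study.group_labels)
    out.to_csv(path, index=False, columns=list(COLUMNS))


def extract_pair(study: StudyTable, time_curr: float) -> TimepointPairData:
    """Build the adjacent-time-point paired vectors for one comparison.

    ``time_prev`` is the immediately preceding *observed* time point in
    sorted numeric order; irregular spacing is allowed and no spacing
    adjustment is made.  Within each group only animals measured at both
    times are retained (complete-case pairing), in stable animal-id order;
    dropped counts are recorded per group.

    Raises
    ------
    PairExtractionError
        If ``time_curr`` is not observed, is the earliest time point, or a
        group retains zero complete pairs.
    """
    times = study.times
    idx = np.flatnonzero(np.isclose(times, float(time_curr)))
    if idx.size == 0:
        raise PairExtractionError(f"time {time_curr!r} is not an observed time point")
    if idx[0] == 0:
        raise PairExtractionError(
            f"time {time_curr!r} is the earliest time point: no preceding time point"
        )
    t_curr = float(times[idx[0]])
    t_prev = float(times[idx[0] - 1])

    df = study.data
    vectors: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    dropped: dict[int, int] = {}
    for g in (0, 1):
        sub = df[df["group"] == g]
        prev = sub[np.isclose(sub["time"], t_prev)].set_index("animal_id")["volume"]
        curr = sub[np.isclose(sub["time"], t_curr)].set_index("animal_id")["volume"]
        ids = sorted(set(prev.index) & set(curr.index))
        n_group = sub["animal_id"].nunique()
        dropped[g] = n_group - len(ids)
        if not ids:
            raise PairExtractionError(
                f"group {study.group_labels.get(g, g)} has no animal measured at both "
                f"t={t_prev:g} and t={t_curr:g}"
            )
        vectors[g] = (prev.loc[ids].to_numpy(float), curr.loc[ids].to_numpy(float))

    pair = TimepointPairData(
        time_prev=t_prev,
        time_curr=t_curr,
        y_prev_0=vectors[0][0],
        y_curr_0=vectors[0][1],
        y_prev_1=vectors[1][0],
        y_curr_1=vectors[1][1],
        group_labels=dict(study.group_labels),
        dropped=dropped,
    )
    return pair


def study_from_records(
    records: Sequence[tuple[str, int, float, float]],
    group_labels: Mapping[int, str] | None = None,
    volume_scale: str = "raw",
) -> StudyTable:
    """Construct a StudyTable directly from (animal_id, group, time, volume) tuples."""
    df = pd.DataFrame(records, columns=list(COLUMNS))
    df["animal_id"] = df["animal_id"].astype(str)
    df["group"] = df["group"].astype(int)
    df["time"] = df["time"].astype(float)
    df["volume"] = df["volume"].astype(float)
    labels = dict(group_labels) if group_labels else {0: "0", 1: "1"}
    study = StudyTable(data=df, group_labels=labels, volume_scale=volume_scale)
    report = validate_study(study, study.report)
    if not report.ok:
        raise StudyValidationError("; ".join(report.errors))
    return study
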