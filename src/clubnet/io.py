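"""Reading and writing of on-disk artifacts.

Handles the cohort manifest (CSV), per-subject parcellated time series
(TSV/CSV, one column per region), and the result tables written at the end
of a pipeline run.  All readers validate strictly and raise
:class:`~clubnet.errors.FormatError` / :class:`~clubnet.errors.ValidationError`
with messages that name the offending row, column or label.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

GROUPS = ("HC", "SCD", "aMCI")
SEXES = ("F", "M")

#: Manifest columns, in canonical order.  The last four scores are optional
#: per row (empty cell -> None) but the columns themselves must exist.
MANIFEST_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "mmse",
    "gds",
    "lmt_immediate",
    "lmt_delayed",
)

SCORE_COLUMNS = ("mmse", "gds", "lmt_immediate", "lmt_delayed")


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the cohort manifest."""

    subject_id: str
    group: str
    age: float
    sex: str
    mmse: float | None = None
    gds: float | None = None
    lmt_immediate: float | None = None
    lmt_delayed: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group label {self.group!r} for subject "
                f"{self.subject_id!r}; expected one of {GROUPS}"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"unknown sex label {self.sex!r} for subject {self.subject_id!r}"
            )
        if not self.age > 0:
            raise ValidationError(
                f"age must be positive, got {self.age} for {self.subject_id!r}"
            )


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region labels; 0-based indices internally, labels in reports."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("atlas labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @classmethod
    def aal90(cls) -> "RegionAtlas":
        """The bundled 90-region AAL atlas (abbreviated labels)."""
        text = resources.files("clubnet").joinpath(
            "data/aal90_labels.txt").read_text()
        labels = tuple(line.strip() for line in text.splitlines() if line.strip())
        if len(labels) != 90:
            raise ValidationError("bundled atlas must have 90 labels")
        return cls(labels)


@dataclass
class TimeSeriesMatrix:
    """One subject's parcellated signal: T timepoints x N regions."""

    values: np.ndarray
    region_labels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("time series must be a 2-D matrix")
        if self.values.shape[1] != len(self.region_labels):
            raise ValidationError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.region_labels)} region labels"
            )
        if self.values.shape[0] < 3:
            raise ValidationError("need at least 3 timepoints")
        if not np.isfinite(self.values).all():
            raise ValidationError(
                f"non-finite values in time series for {self.subject_id!r}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def read_manifest(path: str | os.PathLike) -> list[SubjectRecord]:
    """Read a cohort manifest CSV into a list of :class:`SubjectRecord`.

    Rows are returned in file order.  Missing cognitive scores (empty cells)
    become ``None``; a missing *column* is a format error.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "sex": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} is missing required columns: {missing}")
    records: list[SubjectRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        # +2: 1-based file line, accounting for the header line.
        line = i + 2
        group = getattr(row, "group")
        if group not in GROUPS:
            raise ValidationError(
                f"row {line} of {path}: unknown group label {group!r} "
                f"(expected one of {GROUPS})"
            )
        scores = {}
        for col in SCORE_COLUMNS:
            v = getattr(row, col)
            scores[col] = None if pd.isna(v) else float(v)
        try:
            rec = SubjectRecord(
                subject_id=str(getattr(row, "subject_id")),
                group=group,
                age=float(getattr(row, "age")),
                sex=str(getattr(row, "sex")),
                **scores,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {line} of {path}: {exc}") from exc
        records.append(rec)
    log.info("read %d subject records from %s", len(records), path)
    return records


def write_manifest(records: Sequence[SubjectRecord], path: str | os.PathLike) -> None:
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(SubjectRecord)}
        rows.append(d)
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_timeseries(
    path: str | os.PathLike,
    atlas: RegionAtlas,
    subject_id: str = "",
) -> TimeSeriesMatrix:
    """Read a delimited time-series file (header = region labels).

    Columns are reordered to atlas order when they are a permutation of the
    atlas labels; any set difference is an error listing the mismatch.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    file_labels = [str(c) for c in df.columns]
    if set(file_labels) != set(atlas.labels):
        missing = sorted(set(atlas.labels) - set(file_labels))
        extra = sorted(set(file_labels) - set(atlas.labels))
        raise FormatError(
            f"{path}: region labels do not match atlas; "
            f"missing={missing} unexpected={extra}"
        )
    try:
        values = df[list(atlas.labels)].to_numpy(dtype=float)
    except (TypeError, ValueError):
        obj = df[list(atlas.labels)].to_numpy(dtype=object)
        for (r, c), v in np.ndenumerate(obj):
            try:
                float(v)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric cell {v!r} at data row {r + 1}, "
                    f"column {atlas.labels[c]!r}"
                ) from None
        raise  # pragma: no cover - unreachable if scan above found the cell
    ts = TimeSeriesMatrix(values, atlas.labels, subject_id=subject_id or path.stem)
    log.info("read time series %s: T=%d N=%d", path, ts.n_timepoints, ts.n_regions)
    return ts


def write_timeseries(ts: TimeSeriesMatrix, path: str | os.PathLike) -> None:
    path = Path(path)
    df = pd.DataFrame(ts.values, columns=list(ts.region_labels))
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.10g",
              lineterminator="\n")


# ---------------------------------------------------------------------------
# Result bundle
# ---------------------------------------------------------------------------

METRIC_TABLE_COLUMNS = [
    "subject_id", "group", "Cp", "Lp", "Eg", "Eloc", "gamma", "lambda", "sigma",
]
NODAL_TABLE_COLUMNS = [
    "subject_id", "group", "region", "degree", "nodal_efficiency",
    "nodal_clustering", "nodal_Lp", "betweenness", "participation",
]
STRENGTH_TABLE_COLUMNS = [
    "subject_id", "group", "criterion",
    "club_strength", "feeder_strength", "local_strength",
]
STATS_TABLE_COLUMNS = [
    "metric", "contrast", "statistic", "value", "df1", "df2",
    "p_raw", "p_bonferroni", "n", "covariates",
]


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


@dataclass
class ResultBundle:
    """Everything one pipeline run produces, ready for :func:`write_results`."""

    metrics: pd.DataFrame = field(default_factory=lambda: _empty(METRIC_TABLE_COLUMNS))
    nodal_metrics: pd.DataFrame = field(
        default_factory=lambda: _empty(NODAL_TABLE_COLUMNS))
    clubs: dict = field(
        default_factory=lambda: {"rich_club": [], "diverse_club": [], "overlap": []})
    strengths: pd.DataFrame = field(
        default_factory=lambda: _empty(STRENGTH_TABLE_COLUMNS))
    stats: pd.DataFrame = field(default_factory=lambda: _empty(STATS_TABLE_COLUMNS))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g",
              lineterminator="\n")


def write_results(results: ResultBundle, out_dir: str | os.PathLike) -> list[Path]:
    """Write the deterministic result file set; returns the written paths.

    Identical bundles produce byte-identical files.  The directory is checked
    for writability up front so a failure never leaves a partial stats.tsv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise OSError(f"output directory {out} is not writable")
    written: list[Path] = []
    for name, df in (
        ("metrics.tsv", results.metrics),
        ("nodal_metrics.tsv", results.nodal_metrics),
        ("strengths.tsv", results.strengths),
    ):
        _write_tsv(df, out / name)
        written.append(out / name)
    clubs_path = out / "clubs.json"
    clubs_path.write_text(
        json.dumps(results.clubs, indent=2, sort_keys=True) + "\n")
    written.append(clubs_path)
    _write_tsv(results.stats, out / "stats.tsv")
    written.append(out / "stats.tsv")
    log.info("wrote %d result files to %s", len(written), out)
    return written


def read_clubs(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def scores_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Manifest records as a DataFrame (for statistics; None stays NaN)."""
    return pd.DataFrame(
        [{f.name: getattr(r, f.name) for f in fields(SubjectRecord)}
         for r in records],
        columns=list(MANIFEST_COLUMNS),
    )
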