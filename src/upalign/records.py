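"""Prediction-record tables: domain types and CSV/JSON readers and writers.

The atom of the package is one model prediction for one image: a continuous
score in [0, 1] together with its case, image and device identifiers, an
optional binary ground-truth label, and a time index in weeks.  Cases group
images (in screening mammography, four views per study); all images of a
case share its label, device and time index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

COLUMNS = ["score", "label", "case_id", "image_id", "device_id", "time_index"]
MANDATORY_COLUMNS = ["score", "case_id", "image_id", "device_id"]

__all__ = [
    "PredictionRecord",
    "RecordSet",
    "read_records",
    "write_records",
    "SchemaError",
    "ScoreParseError",
    "RecordValidationError",
    "MissingLabelError",
]


class SchemaError(ValueError):
    """A mandatory column is absent from the input table."""


class ScoreParseError(ValueError):
    """A score cell could not be parsed as a number."""


class RecordValidationError(ValueError):
    """A record violates an invariant (range, uniqueness, case consistency)."""


class MissingLabelError(ValueError):
    """Labels were requested but at least one record is unlabelled."""


@dataclass(frozen=True)
class PredictionRecord:
    """A single model prediction with its metadata."""

    score: float
    case_id: str
    image_id: str
    device_id: str
    label: Optional[int] = None
    time_index: int = 0


class RecordSet:
    """An ordered collection of prediction records backed by a DataFrame.

    Labels are stored as floats with NaN for missing so that partially
    labelled sets (alignment sets need no labels) are first-class.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        df = frame.copy()
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        if "label" not in df.columns:
            df["label"] = np.nan
        if "time_index" not in df.columns:
            df["time_index"] = 0
        df = df[COLUMNS].reset_index(drop=True)
        df["score"] = df["score"].astype(np.float64)
        df["label"] = pd.to_numeric(df["label"], errors="coerce").astype(np.float64)
        df["time_index"] = (
            pd.to_numeric(df["time_index"], errors="coerce").fillna(0).astype(np.int64)
        )
        for col in ("case_id", "image_id", "device_id"):
            df[col] = df[col].astype(str)
        self._df = df
        if validate:
            self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[PredictionRecord]) -> "RecordSet":
        rows = [
            {
                "score": r.score,
                "label": np.nan if r.label is None else float(r.label),
                "case_id": r.case_id,
                "image_id": r.image_id,
                "device_id": r.device_id,
                "time_index": r.time_index,
            }
            for r in records
        ]
        if not rows:
            return cls.empty()
        return cls(pd.DataFrame(rows))

    @classmethod
    def empty(cls) -> "RecordSet":
        return cls(pd.DataFrame({c: [] for c in COLUMNS}), validate=False)

    @classmethod
    def concat(cls, parts: Sequence["RecordSet"]) -> "RecordSet":
        frames = [p._df for p in parts if len(p)]
        if not frames:
            return cls.empty()
        return cls(pd.concat(frames, ignore_index=True))

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        df = self._df
        if len(df) == 0:
            return
        bad = ~np.isfinite(df["score"].to_numpy()) | (df["score"] < 0) | (df["score"] > 1)
        if bad.any():
            rows = (np.flatnonzero(bad) + 1).tolist()
            raise RecordValidationError(
                f"score outside [0, 1] (or non-finite) at row(s) {rows[:10]}"
            )
        lab = df["label"].to_numpy()
        present = ~np.isnan(lab)
        if present.any() and not np.isin(lab[present], (0.0, 1.0)).all():
            rows = (np.flatnonzero(present & ~np.isin(lab, (0.0, 1.0))) + 1).tolist()
            raise RecordValidationError(f"label not in {{0, 1}} at row(s) {rows[:10]}")
        if (df["time_index"] < 0).any():
            raise RecordValidationError("negative time_index")
        dup = df.duplicated(subset=["case_id", "image_id"])
        if dup.any():
            rows = (np.flatnonzero(dup.to_numpy()) + 1).tolist()
            raise RecordValidationError(
                f"duplicate (case_id, image_id) at row(s) {rows[:10]}"
            )
        per_case = df.groupby("case_id", sort=False).agg(
            device=("device_id", "nunique"),
            time=("time_index", "nunique"),
            label=("label", lambda s: s.dropna().nunique()),
        )
        incons = per_case[(per_case > 1).any(axis=1)]
        if len(incons):
            raise RecordValidationError(
                "images of one case must share device_id, time_index and label; "
                f"inconsistent case(s): {list(incons.index[:5])}"
            )

    # -- accessors ----------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def scores(self) -> np.ndarray:
        return self._df["score"].to_numpy()

    @property
    def has_labels(self) -> bool:
        return len(self._df) > 0 and not self._df["label"].isna().any()

    @property
    def labels(self) -> np.ndarray:
        lab = self._df["label"].to_numpy()
        if np.isnan(lab).any():
            raise MissingLabelError("labels requested but some records are unlabelled")
        return lab.astype(np.int64)

    @property
    def prevalence(self) -> float:
        """Fraction of positive images; requires every record labelled."""
        lab = self.labels
        return float(lab.mean())

    @property
    def case_ids(self) -> np.ndarray:
        return self._df["case_id"].unique()

    @property
    def n_cases(self) -> int:
        return int(self._df["case_id"].nunique())

    def for_device(self, device_id: str) -> "RecordSet":
        sub = self._df[self._df["device_id"] == device_id]
        out = RecordSet.empty()
        out._df = sub.reset_index(drop=True)
        return out

    def at_time(self, time_index: int) -> "RecordSet":
        sub = self._df[self._df["time_index"] == time_index]
        out = RecordSet.empty()
        out._df = sub.reset_index(drop=True)
        return out

    def iter_records(self):
        for row in self._df.itertuples(index=False):
            yield PredictionRecord(
                score=float(row.score),
                label=None if np.isnan(row.label) else int(row.label),
                case_id=row.case_id,
                image_id=row.image_id,
                device_id=row.device_id,
                time_index=int(row.time_index),
            )

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RecordSet):
            return NotImplemented
        a, b = self._df, other._df
        if len(a) != len(b):
            return False
        if len(a) == 0:
            return True
        return all(
            (
                np.array_equal(
                    a[c].to_numpy(), b[c].to_numpy(), equal_nan=(c == "label")
                )
                if c in ("score", "label", "time_index")
                else (a[c] == b[c]).all()
            )
            for c in COLUMNS
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RecordSet(n={len(self)}, cases={self.n_cases})"


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_records(path, format: Optional[str] = None) -> RecordSet:
    """Read a prediction-record table from CSV or JSON.

    Raises :class:`SchemaError` if a mandatory column is missing,
    :class:`ScoreParseError` (with the 1-based data-row number) for a
    non-numeric score, and :class:`RecordValidationError` for out-of-range
    values.  No row is ever silently dropped.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.read_csv(
            path,
            dtype={"case_id": str, "image_id": str, "device_id": str},
            float_precision="round_trip",
        )
    elif fmt == "json":
        with open(path) as fh:
            rows = json.load(fh)
        df = pd.DataFrame(rows, columns=COLUMNS if not rows else None)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    raw = df["score"]
    coerced = pd.to_numeric(raw, errors="coerce")
    bad = coerced.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ScoreParseError(f"non-numeric score at data row {row}: {raw.iloc[row - 1]!r}")
    df["score"] = coerced
    return RecordSet(df)


def write_records(rs: RecordSet, path, format: Optional[str] = None) -> None:
    """Write a record set losslessly; scores keep full precision.

    CSV: comma-separated UTF-8 with a mandatory header; missing labels are
    empty cells.  JSON: an array of objects with the same keys (missing
    label is ``null``).  Output is byte-stable for a given record set.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    df = rs.frame.copy()
    if fmt == "csv":
        # repr-based float formatting is the shortest round-trip representation
        df["label"] = df["label"].map(
            lambda v: "" if np.isnan(v) else repr(int(v))
        )
        df["score"] = df["score"].map(repr)
        df.to_csv(path, index=False)
    elif fmt == "json":
        rows = []
        for row in df.itertuples(index=False):
            rows.append(
                {
                    "score": float(row.score),
                    "label": None if np.isnan(row.label) else int(row.label),
                    "case_id": row.case_id,
                    "image_id": row.image_id,
                    "device_id": row.device_id,
                    "time_index": int(row.time_index),
                }
            )
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")
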