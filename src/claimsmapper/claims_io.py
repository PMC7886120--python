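"""Claims ingestion, cohort extraction, and history binarization.

Claims are long-format diagnosis events: one row per (patient, ICD-10
code, service date).  The cohort is every patient with at least one claim
carrying the index diagnosis category (e.g. F32, major depressive
disorder); the index date is that patient's earliest such claim.  Each
cohort member contributes two code *sets*: the medical histories recorded
in a lookback window before the index date and the complications in a
follow-up window after it.  Multiplicity and within-window timing are
deliberately discarded — the analysis treats a history as a yes/no
variable per patient.

Window convention: pre = [index - pre_window_days, index), closed on the
left, open at the index date; post = (index, index + post_window_days],
open at the index date, closed on the right.  Same-day claims other than
the index code belong to neither window.  Codes are aggregated to
3-character ICD-10 categories before any set is formed, and the index
category itself is excluded from both sets.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ClaimsFormatError, ConfigError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("patient_id", "code", "date")

#: codes already warned about by :func:`truncate_code` (log once per code)
_SHORT_CODE_WARNED: set[str] = set()


@dataclass(frozen=True)
class ClaimsTable:
    """Long-format claims: columns ``patient_id``, ``code``, ``date``.

    Duplicate (patient, code, date) triples are permitted — repeat claims
    are common in billing data — and row order carries no meaning: every
    downstream result is invariant under permutation of the rows.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigError(f"claims table missing column(s): {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, date]]
    ) -> "ClaimsTable":
        rows = list(records)
        df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
        df["patient_id"] = df["patient_id"].astype(str)
        df["code"] = df["code"].astype(str).str.strip().str.upper()
        df["date"] = pd.to_datetime(df["date"])
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort definition: index category and window lengths.

    ``require_full_windows`` drops patients whose observed claim span
    does not cover both complete windows; off by default because it
    changes the cohort size t.
    """

    index_code: str = "F32"
    pre_window_days: int = 730
    post_window_days: int = 730
    require_full_windows: bool = False

    def __post_init__(self) -> None:
        if self.pre_window_days <= 0 or self.post_window_days <= 0:
            raise ConfigError("window lengths must be positive")
        if len(self.index_code) != 3:
            raise ConfigError(
                f"index_code must be a 3-character category, got "
                f"{self.index_code!r}"
            )


@dataclass(frozen=True)
class PatientJourney:
    """One cohort member: index date plus pre/post code-category sets."""

    patient_id: str
    index_date: date
    pre_codes: frozenset[str]
    post_codes: frozenset[str]


@dataclass(frozen=True)
class PatientItemMatrix:
    """Patient x code binary membership matrix for one window.

    Rows follow ``patient_ids`` (cohort order, sorted by patient id);
    columns follow ``codes`` in lexicographic order, so the encoding is
    deterministic regardless of input record order.
    """

    patient_ids: tuple[str, ...]
    codes: tuple[str, ...]
    values: np.ndarray = field(repr=False)  # bool, shape (n_patients, n_codes)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.patient_ids), len(self.codes)):
            raise ValueError("membership matrix shape mismatch")

    @property
    def t(self) -> int:
        """Cohort size (row count); the denominator of support."""
        return len(self.patient_ids)

    def column(self, code: str) -> np.ndarray:
        try:
            j = self.codes.index(code)
        except ValueError:
            raise KeyError(f"unknown code category: {code!r}") from None
        return self.values[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int),
            index=list(self.patient_ids),
            columns=list(self.codes),
        )


def truncate_code(code: str) -> str:
    """Aggregate an ICD-10 code to its 3-character category.

    "F320" -> "F32", "k29.1" -> "K29".  Codes shorter than three
    characters are returned unchanged (upper-cased) with a one-time
    warning per code.
    """
    if not code:
        raise ValueError("empty diagnosis code")
    code = code.strip().upper()
    if len(code) < 3:
        if code not in _SHORT_CODE_WARNED:
            _SHORT_CODE_WARNED.add(code)
            logger.warning("code %r shorter than 3 characters; kept as-is", code)
        return code
    return code[:3]


def read_claims(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> ClaimsTable:
    """Read delimited claims text into a :class:`ClaimsTable`.

    The separator is auto-detected from the extension (``.tsv``/``.tab``
    -> tab, otherwise comma).  ``dialect`` maps the standard column roles
    to the file's header names via keys ``patient_col``, ``code_col``,
    ``date_col``; omitted keys default to the standard names.  Dates must
    be ISO-8601.

    Raises :class:`ConfigError` naming any configured column absent from
    the header, and :class:`ClaimsFormatError` with the 1-based data line
    number for an unparseable date.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    dialect = dict(dialect or {})
    colmap = {
        "patient_id": dialect.get("patient_col", "patient_id"),
        "code": dialect.get("code_col", "code"),
        "date": dialect.get("date_col", "date"),
    }
    df = pd.read_csv(path, sep=sep, dtype=str)
    for role, col in colmap.items():
        if col not in df.columns:
            raise ConfigError(
                f"column {col!r} (for {role}) not found in {path.name}; "
                f"header has {list(df.columns)}"
            )
    df = df[[colmap["patient_id"], colmap["code"], colmap["date"]]].copy()
    df.columns = list(REQUIRED_COLUMNS)
    df["patient_id"] = df["patient_id"].astype(str).str.strip()
    df["code"] = df["code"].astype(str).str.strip().str.upper()
    parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = parsed.isna() & df["date"].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
        raise ClaimsFormatError(
            f"unparseable date {df['date'].iloc[line - 1]!r} "
            f"at data line {line} of {path.name}"
        )
    if parsed.isna().any():
        line = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 1
        raise ClaimsFormatError(f"missing date at data line {line} of {path.name}")
    df["date"] = parsed
    if (df["code"] == "").any():
        line = int(np.flatnonzero((df["code"] == "").to_numpy())[0]) + 1
        raise ClaimsFormatError(f"empty code at data line {line} of {path.name}")
    return ClaimsTable(df)


def extract_cohort(
    claims: ClaimsTable, spec: CohortSpec | None = None
) -> list[PatientJourney]:
    """Extract the index-diagnosis cohort as a sorted list of journeys.

    A patient enters the cohort iff at least one claim truncates to the
    index category; the index date is the earliest such claim.  Pre/post
    code sets are built from truncated categories within the half-open
    windows described in the module docstring, always excluding the index
    category itself.  An empty cohort is returned as an empty list.
    """
    spec = spec or CohortSpec()
    if len(claims) == 0:
        raise ValueError("claims table is empty")
    df = claims.df.copy()
    df["category"] = [truncate_code(c) for c in df["code"]]

    index_rows = df[df["category"] == spec.index_code]
    if index_rows.empty:
        logger.info("no patient carries index code %s; empty cohort", spec.index_code)
        return []
    index_dates = index_rows.groupby("patient_id")["date"].min()

    cohort_df = df[df["patient_id"].isin(index_dates.index)].copy()
    cohort_df["index_date"] = cohort_df["patient_id"].map(index_dates)
    offset = (cohort_df["date"] - cohort_df["index_date"]).dt.days
    not_index_cat = cohort_df["category"] != spec.index_code
    pre_mask = (offset >= -spec.pre_window_days) & (offset < 0) & not_index_cat
    post_mask = (offset > 0) & (offset <= spec.post_window_days) & not_index_cat

    pre_sets = cohort_df[pre_mask].groupby("patient_id")["category"].agg(frozenset)
    post_sets = cohort_df[post_mask].groupby("patient_id")["category"].agg(frozenset)

    if spec.require_full_windows:
        span = cohort_df.groupby("patient_id")["date"].agg(["min", "max"])
        lo_ok = span["min"] <= index_dates - pd.Timedelta(days=spec.pre_window_days)
        hi_ok = span["max"] >= index_dates + pd.Timedelta(days=spec.post_window_days)
        keep = index_dates.index[(lo_ok & hi_ok).reindex(index_dates.index)]
    else:
        keep = index_dates.index

    journeys = [
        PatientJourney(
            patient_id=str(pid),
            index_date=index_dates[pid].date(),
            pre_codes=pre_sets.get(pid, frozenset()),
            post_codes=post_sets.get(pid, frozenset()),
        )
        for pid in sorted(keep)
    ]
    if not journeys:
        logger.info("cohort empty after full-window filtering")
    return journeys


def binarize(
    journeys: Sequence[PatientJourney], window: Literal["pre", "post"]
) -> PatientItemMatrix:
    """Encode one window's code sets as a patient x code binary matrix.

    Every journey contributes a row even when its code set is empty (the
    patient still counts toward the cohort size t).  Columns are the
    distinct categories observed in the chosen window, sorted
    lexicographically.
    """
    if window not in ("pre", "post"):
        raise ValueError(f"window must be 'pre' or 'post', got {window!r}")
    if not journeys:
        raise ValueError("no journeys to binarize")
    code_sets = [
        j.pre_codes if window == "pre" else j.post_codes for j in journeys
    ]
    codes = tuple(sorted(set().union(*code_sets)))
    col = {c: i for i, c in enumerate(codes)}
    values = np.zeros((len(journeys), len(codes)), dtype=bool)
    for i, s in enumerate(code_sets):
        for c in s:
            values[i, col[c]] = True
    return PatientItemMatrix(
        patient_ids=tuple(j.patient_id for j in journeys),
        codes=codes,
        values=values,
    )


def write_cohort_summary(
    journeys: Sequence[PatientJourney], path: str | Path
) -> None:
    """Write the per-patient cohort summary CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "index_date", "n_pre_codes", "n_post_codes"])
        for j in journeys:
            w.writerow(
                [j.patient_id, j.index_date.isoformat(), len(j.pre_codes), len(j.post_codes)]
            )
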