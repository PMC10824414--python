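"""Delimited-text I/O and validated in-memory tables.

All inputs and outputs are comma-separated UTF-8 with a mandatory header
row.  The two experimental tables are

* ``wells.csv`` — one row per cultured well:
  ``age_weeks,mouse_id,well_id,proportion`` where ``proportion`` is the
  fraction of CD201+CD150+KSL cells among all expanded cells, stored as a
  decimal in [0, 1];
* ``census.csv`` — one row per (age, bone, mouse):
  ``age_weeks,bone,mouse_id,hsc_count,ksl_count`` with ``bone`` one of
  femur / pelvis / sternum and HSCs a subset of KSL
  (``hsc_count <= ksl_count``).

Validation is total: malformed files raise :class:`FormatError` or
:class:`ValidationError` naming the offending rows; a partial table is never
returned.  Row numbers in diagnostics are 1-based data rows (the header is
row 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

BONES = ("femur", "pelvis", "sternum")

WELL_COLUMNS = ["age_weeks", "mouse_id", "well_id", "proportion"]
CENSUS_COLUMNS = ["age_weeks", "bone", "mouse_id", "hsc_count", "ksl_count"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _bad_rows(mask: pd.Series) -> list[int]:
    # positional 1-based data-row numbers
    return [int(i) + 1 for i in np.flatnonzero(mask.to_numpy())]


@dataclass
class WellProportionTable:
    """Per-well CD201+CD150+KSL proportions keyed by (age, mouse, well)."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        _require_columns(df, WELL_COLUMNS, "WellProportionTable")
        bad = _bad_rows(~(df["age_weeks"] > 0))
        if bad:
            raise ValidationError(f"column age_weeks must be > 0; offending row(s) {bad}")
        bad = _bad_rows(~((df["proportion"] >= 0) & (df["proportion"] <= 1)))
        if bad:
            raise ValidationError(f"column proportion must lie in [0, 1]; offending row(s) {bad}")
        dup = df.duplicated(subset=["age_weeks", "mouse_id", "well_id"], keep=False)
        if dup.any():
            raise ValidationError(
                f"(age_weeks, mouse_id, well_id) must be unique; offending row(s) {_bad_rows(dup)}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WellProportionTable):
            return NotImplemented
        return self.df[WELL_COLUMNS].equals(other.df[WELL_COLUMNS])

    def ages(self) -> np.ndarray:
        return np.sort(self.df["age_weeks"].unique())


@dataclass
class CensusSeries:
    """Bone-marrow HSC and KSL counts per (age, bone, mouse).

    ``hsc_count`` observes the stem compartment S(t); ``ksl_count`` observes
    S(t) + P(t).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        _require_columns(df, CENSUS_COLUMNS, "CensusSeries")
        unknown = ~df["bone"].isin(BONES)
        if unknown.any():
            raise FormatError(
                f"column bone must be one of {BONES}; offending row(s) {_bad_rows(unknown)}"
            )
        bad = _bad_rows(~(df["age_weeks"] > 0))
        if bad:
            raise ValidationError(f"column age_weeks must be > 0; offending row(s) {bad}")
        bad = _bad_rows(~(df["hsc_count"] >= 0) | ~(df["ksl_count"] >= 0))
        if bad:
            raise ValidationError(f"counts must be nonnegative; offending row(s) {bad}")
        bad = _bad_rows(df["hsc_count"] > df["ksl_count"])
        if bad:
            raise ValidationError(
                f"column hsc_count must not exceed ksl_count (HSCs are a KSL subset); "
                f"offending row(s) {bad}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CensusSeries):
            return NotImplemented
        return self.df[CENSUS_COLUMNS].equals(other.df[CENSUS_COLUMNS])

    def restrict_bone(self, bone: str) -> "CensusSeries":
        if bone not in BONES:
            raise FormatError(f"unknown bone {bone!r}; expected one of {BONES}")
        return CensusSeries(self.df[self.df["bone"] == bone].reset_index(drop=True))


def _read_csv(path, dtypes: dict) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: cannot parse as CSV: {exc}") from exc
    for col, dtype in dtypes.items():
        if col not in df.columns:
            continue
        if dtype is float:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = _bad_rows(coerced.isna() & df[col].notna())
            if bad:
                raise FormatError(f"{path}: column {col} has non-numeric value(s) in row(s) {bad}")
            df[col] = coerced.astype(float)
        else:
            df[col] = df[col].astype(str)
    return df


def read_well_proportions(path) -> WellProportionTable:
    """Read and validate a wells CSV (columns ``age_weeks, mouse_id, well_id,
    proportion``)."""
    df = _read_csv(path, {"age_weeks": float, "mouse_id": str, "well_id": str, "proportion": float})
    _require_columns(df, WELL_COLUMNS, path)
    return WellProportionTable(df[WELL_COLUMNS])


def read_census(path) -> CensusSeries:
    """Read and validate a census CSV (columns ``age_weeks, bone, mouse_id,
    hsc_count, ksl_count``)."""
    df = _read_csv(
        path,
        {"age_weeks": float, "bone": str, "mouse_id": str, "hsc_count": float, "ksl_count": float},
    )
    _require_columns(df, CENSUS_COLUMNS, path)
    return CensusSeries(df[CENSUS_COLUMNS])


def write_table(records, path) -> None:
    """Write a result table as CSV with header.

    ``records`` may be a :class:`WellProportionTable`, :class:`CensusSeries`
    or a plain DataFrame.  Floats are written in shortest round-tripping
    decimal form, so ``read(write(T)) == T`` exactly.
    """
    df = records.df if hasattr(records, "df") else records
    if len(df) == 0:
        raise ValidationError("refusing to write an empty table")
    # shortest decimal representation that round-trips the binary double
    # 17 significant digits uniquely identify a binary double, so the
    # read-back (with a correctly-rounded parser) equals the written value
    df.to_csv(path, index=False, float_format="%.17g")
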