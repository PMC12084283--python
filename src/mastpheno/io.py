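"""Observation, roster and climate tables; phenological-year bookkeeping.

Observations are long-format monthly records: one row per
``(tree_id, date, phenophase)`` carrying an ordinal intensity score 0-4
(0 = phenophase absent; 1-4 = quartiles of canopy-relative magnitude).
The phenological year runs August-July, matching the austral-summer
growing season: a date in [1 Aug y, 31 Jul y+1] belongs to pheno-year y.

Missing visits are absent rows, never zeros -- a 0 score is a biological
observation (absence of the phenophase), not missingness.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOPHASES = ("leaf", "flower", "fruit")
SITES = ("Nk", "Sk", "Su")
SCORE_MIN = 0
SCORE_MAX = 4
#: number of ordinal classes J (scores 0..4)
N_CLASSES = 5

OBS_COLUMNS = ["tree_id", "species", "site", "date", "phenophase", "score"]
ROSTER_COLUMNS = ["tree_id", "species", "site", "active_from", "active_to"]
CLIMATE_COLUMNS = ["week_start_date", "temperature", "precip", "radiation"]


class ValidationError(ValueError):
    """Raised when an input table violates the data contract."""


def pheno_year_of(date) -> int:
    """Phenological-year label (August-July cycle) of a calendar date.

    A date in [1 Aug y, 31 Jul y+1] maps to label y.
    """
    ts = pd.Timestamp(date)
    return ts.year if ts.month >= 8 else ts.year - 1


def doy_365(date) -> int:
    """Day of year in a fixed 365-day convention.

    29 February is mapped onto the DOY of 28 February (59) and later dates
    in a leap year are shifted down by one, so the circular modulus is a
    constant 365 in every year.
    """
    ts = pd.Timestamp(date)
    doy = ts.dayofyear
    if ts.is_leap_year and doy >= 60:
        doy -= 1
    return int(doy)


def _doy_365_vec(dates: pd.Series) -> np.ndarray:
    dt = pd.DatetimeIndex(dates)
    doy = dt.dayofyear.to_numpy().astype(int)
    shift = dt.is_leap_year & (doy >= 60)
    return doy - shift.astype(int)


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an observation table in place and return it.

    Checks column presence, parseable ISO dates, known phenophases and
    sites, integer scores in [0, 4], and uniqueness of
    (tree_id, date, phenophase). Raises :class:`ValidationError` naming the
    first offending row.
    """
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"observation table missing columns: {missing}")
    if len(df) == 0:
        raise ValidationError("observation table is empty")

    df = df.copy()
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable date in observations: {exc}") from exc

    bad_phase = ~df["phenophase"].isin(PHENOPHASES)
    if bad_phase.any():
        row = df.index[bad_phase][0]
        raise ValidationError(
            f"row {row}: unknown phenophase {df.loc[row, 'phenophase']!r} "
            f"(expected one of {PHENOPHASES})"
        )

    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = scores.isna() | (scores != scores.round()) | (scores < SCORE_MIN) | (scores > SCORE_MAX)
    if bad.any():
        row = df.index[bad][0]
        raise ValidationError(
            f"row {row}: score {df.loc[row, 'score']!r} outside the ordinal "
            f"range {SCORE_MIN}..{SCORE_MAX}"
        )
    df["score"] = scores.astype(int)

    dup = df.duplicated(subset=["tree_id", "date", "phenophase"], keep=False)
    if dup.any():
        row = df.index[dup][0]
        key = tuple(df.loc[row, ["tree_id", "date", "phenophase"]])
        raise ValidationError(f"duplicate (tree, date, phenophase) key {key} at row {row}")

    return df


def read_observations(path) -> pd.DataFrame:
    """Read and validate a long-format observation CSV.

    Expected header: ``tree_id,species,site,date,phenophase,score`` with
    ISO-8601 dates and integer scores 0-4.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"tree_id": str, "species": str, "site": str})
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty observation file") from exc
    return validate_observations(df)


def write_observations(df: pd.DataFrame, path) -> None:
    """Write an observation table with the canonical column order."""
    out = df.loc[:, OBS_COLUMNS].copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_roster(path) -> pd.DataFrame:
    """Read a tree roster CSV (``active_to`` empty means still active)."""
    df = pd.read_csv(path, dtype={"tree_id": str, "species": str, "site": str})
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"roster missing columns: {missing}")
    df["active_from"] = pd.to_datetime(df["active_from"])
    df["active_to"] = pd.to_datetime(df["active_to"])  # NaT when open
    if df["tree_id"].duplicated().any():
        dup = df.loc[df["tree_id"].duplicated(), "tree_id"].iloc[0]
        raise ValidationError(f"duplicate tree_id {dup!r} in roster")
    return df


def write_roster(df: pd.DataFrame, path) -> None:
    out = df.loc[:, ROSTER_COLUMNS].copy()
    for col in ("active_from", "active_to"):
        out[col] = pd.DatetimeIndex(out[col]).strftime("%Y-%m-%d")
    out["active_to"] = out["active_to"].replace("NaT", "")
    out.to_csv(path, index=False)


def read_climate(path) -> pd.DataFrame:
    """Read weekly climate forcing; enforces strictly 7-day spacing."""
    df = pd.read_csv(path)
    missing = [c for c in CLIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"climate table missing columns: {missing}")
    df["week_start_date"] = pd.to_datetime(df["week_start_date"])
    gaps = df["week_start_date"].diff().dropna()
    if not (gaps == pd.Timedelta(days=7)).all():
        bad = gaps.index[gaps != pd.Timedelta(days=7)][0]
        raise ValidationError(
            f"climate series not weekly at row {bad} "
            f"(gap {gaps.loc[bad]})"
        )
    return df


def write_climate(df: pd.DataFrame, path) -> None:
    out = df.loc[:, CLIMATE_COLUMNS].copy()
    out["week_start_date"] = pd.DatetimeIndex(out["week_start_date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def annualize(
    table: pd.DataFrame,
    roster: pd.DataFrame,
    phenophase: str,
    min_months: int = 6,
) -> pd.DataFrame:
    """Annual intensity series: per tree x pheno-year mean monthly score.

    Parameters
    ----------
    table
        Validated observation table.
    roster
        Tree roster; every observed tree must appear.
    phenophase
        One of ``leaf``, ``flower``, ``fruit``.
    min_months
        Minimum observed months in a pheno-year for the annual value to be
        emitted; years with fewer observations become missing (dropped).
        Default 6: half-year coverage bounds the bias from deaths and
        August replacements while retaining replacement trees' first years.

    Returns
    -------
    DataFrame with columns ``tree_id, species, phenophase, pheno_year,
    intensity, n_months``, one row per emitted (tree, year).
    """
    if phenophase not in PHENOPHASES:
        raise ValueError(f"unknown phenophase {phenophase!r}")
    sub = table.loc[table["phenophase"] == phenophase].copy()
    unknown = set(sub["tree_id"]) - set(roster["tree_id"])
    if unknown:
        raise ValidationError(f"trees absent from roster: {sorted(unknown)[:5]}")

    sub["pheno_year"] = [pheno_year_of(d) for d in sub["date"]]
    grouped = sub.groupby(["tree_id", "species", "pheno_year"], as_index=False).agg(
        intensity=("score", "mean"), n_months=("score", "size")
    )
    short = grouped["n_months"] < min_months
    if short.any():
        logger.info(
            "annualize(%s): dropping %d tree-years with < %d observed months",
            phenophase, int(short.sum()), min_months,
        )
    out = grouped.loc[~short].copy()
    out.insert(2, "phenophase", phenophase)
    return out.reset_index(drop=True)


def annual_series_matrix(annual: pd.DataFrame) -> pd.DataFrame:
    """Pivot an annualized table to a (tree x pheno-year) intensity matrix."""
    return annual.pivot(index="tree_id", columns="pheno_year", values="intensity")
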