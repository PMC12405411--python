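"""Reading/writing FAERS-style raw tables and FDA-style deduplication.

Two on-disk dialects are supported: the ``$``-delimited ASCII dialect of the
FAERS quarterly extracts, and RFC-4180 CSV with identical columns.  The
XML dialect is out of scope; the three fields the cleaning rule needs
(PRIMARYID, CASEID, FDA_DT) are identical across dialects.

Deduplication follows the FDA-recommended rule: spontaneous reports arrive
in multiple versions when consumers and sponsors both submit a case, so
within each CASEID only the most recent version is kept — the row with the
largest FDA_DT, ties broken by the largest PRIMARYID.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .tables import RawTables, TABLE_COLUMNS, TABLE_NAMES

_DIALECTS = {"ascii": "$", "csv": ","}

#: FAERS age-unit codes → years per unit.  DEC = decades, HR = hours.
AGE_UNIT_TO_YEARS = {
    "YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0, "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25, "HR": 1.0 / 8766.0,
}

_NUMERIC_COLUMNS = {
    "demo": ("fda_dt", "event_dt", "age"),
    "ther": ("start_dt",),
}


def _sep(dialect: str) -> str:
    try:
        return _DIALECTS[dialect]
    except KeyError:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of "
                          f"{sorted(_DIALECTS)}") from None


def table_filename(name: str, dialect: str) -> str:
    return f"{name.upper()}.txt" if dialect == "ascii" else f"{name}.csv"


def write_tables(raw: RawTables, outdir, dialect: str = "ascii") -> None:
    sep = _sep(dialect)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in raw.tables().items():
        df.to_csv(outdir / table_filename(name, dialect), sep=sep, index=False)


def _locate(input_dir: Path, name: str) -> Path:
    hits = sorted(p for p in input_dir.iterdir()
                  if p.is_file() and p.name.lower().startswith(name))
    if not hits:
        raise FormatError(f"no {name.upper()} table found in {input_dir}")
    return hits[0]


def read_tables(source, dialect: str = "ascii") -> RawTables:
    """Parse the five raw tables from a directory (or a ``{name: path}``
    mapping).  Unparseable dates/ages become missing; counts of coerced
    values land in ``RawTables.parse_log``.
    """
    sep = _sep(dialect)
    if isinstance(source, (str, Path)):
        input_dir = Path(source)
        if not input_dir.is_dir():
            raise FormatError(f"input directory {input_dir} does not exist")
        paths = {name: _locate(input_dir, name) for name in TABLE_NAMES}
    else:
        paths = {name: Path(p) for name, p in dict(source).items()}

    frames: dict[str, pd.DataFrame] = {}
    log: dict[str, int] = {}
    for name in TABLE_NAMES:
        path = paths[name]
        if not path.is_file():
            raise FormatError(f"{name.upper()} table {path} does not exist")
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        df.columns = [c.strip().lower() for c in df.columns]
        for col in TABLE_COLUMNS[name]:
            if col not in df.columns:
                raise FormatError(
                    f"{path.name}: required column {col!r} is missing")
        for col in _NUMERIC_COLUMNS.get(name, ()):
            raw_vals = df[col].str.strip()
            parsed = pd.to_numeric(raw_vals, errors="coerce")
            n_bad = int(((raw_vals != "") & parsed.isna()).sum())
            if n_bad:
                log[f"{name}_bad_{col}"] = n_bad
            df[col] = parsed
        frames[name] = df
    return RawTables(**frames, parse_log=log)


def _primaryid_key(primaryid: pd.Series) -> pd.Series:
    """Numeric sort key when every PRIMARYID parses as an integer (the FAERS
    convention), else plain lexicographic strings."""
    numeric = pd.to_numeric(primaryid, errors="coerce")
    if numeric.notna().all():
        return numeric
    return primaryid.astype(str)


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """One row per CASEID: keep max FDA_DT, ties broken by max PRIMARYID.

    Output is sorted by CASEID; rows with missing FDA_DT lose ties against
    any dated version.  Idempotent, and a no-op on duplicate-free input.
    """
    if demo.empty:
        return demo.copy()
    work = demo.assign(_pid_key=_primaryid_key(demo["primaryid"]))
    work = work.sort_values(
        ["caseid", "fda_dt", "_pid_key"],
        kind="mergesort", na_position="first")
    kept = work.drop_duplicates("caseid", keep="last").drop(columns="_pid_key")
    return kept.sort_values("caseid", kind="mergesort").reset_index(drop=True)


def dedup_tables(raw: RawTables) -> RawTables:
    """Deduplicate DEMO and drop child rows of discarded report versions."""
    demo = deduplicate(raw.demo)
    out = raw.select(demo["primaryid"])
    out.demo = demo.reset_index(drop=True)
    out.parse_log = dict(raw.parse_log)
    out.parse_log["n_duplicate_versions_dropped"] = len(raw.demo) - len(demo)
    return out


def normalize_age_years(age: pd.Series, age_cod: pd.Series) -> tuple[pd.Series, int]:
    """Convert (age, unit-code) pairs to years.

    Unknown unit with a value present is treated as years (the dominant
    FAERS convention); the count of such rows is returned for the run log.
    """
    values = pd.to_numeric(age, errors="coerce")
    unit = age_cod.fillna("").astype(str).str.strip().str.upper()
    factor = unit.map(AGE_UNIT_TO_YEARS)
    unknown_unit = values.notna() & factor.isna()
    factor = factor.fillna(1.0)
    return values * factor, int(unknown_unit.sum())
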