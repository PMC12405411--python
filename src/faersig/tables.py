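"""In-memory representation of the FAERS-style raw quarterly tables.

A spontaneous-report dataset is a small relational schema keyed by
``primaryid`` (one row per report *version*): DEMO carries demographics and
administrative fields, DRUG one row per reported drug with its role code,
REAC one row per reaction preferred term (PT), THER therapy start dates and
OUTC outcome codes.  Dates are YYYYMMDD integers, the FAERS convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import pandas as pd

# Columns every dialect must provide (lowercase, as in the FAERS ASCII files).
DEMO_COLUMNS = (
    "primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
    "age", "age_cod", "sex", "reporter_country", "occp_cod",
)
DRUG_COLUMNS = ("primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai")
REAC_COLUMNS = ("primaryid", "caseid", "pt")
THER_COLUMNS = ("primaryid", "caseid", "dsg_drug_seq", "start_dt")
OUTC_COLUMNS = ("primaryid", "caseid", "outc_cod")

TABLE_COLUMNS = {
    "demo": DEMO_COLUMNS,
    "drug": DRUG_COLUMNS,
    "reac": REAC_COLUMNS,
    "ther": THER_COLUMNS,
    "outc": OUTC_COLUMNS,
}
TABLE_NAMES = tuple(TABLE_COLUMNS)


@dataclass
class RawTables:
    """The five raw report tables plus bookkeeping from generation/parsing.

    Invariants: every ``primaryid`` in the child tables exists in ``demo``;
    versions of a duplicated case share ``caseid`` but have distinct,
    increasing ``primaryid`` and non-decreasing ``fda_dt``.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    #: attached by the synthetic generator; None for data read from disk
    ground_truth: Any = None
    #: per-table counts of values that failed to parse (set by the reader)
    parse_log: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_NAMES}

    def n_rows(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.tables().items()}

    def select(self, primaryids: Iterable) -> "RawTables":
        """Restrict every table to the given report versions."""
        keep = pd.Index(pd.unique(pd.Series(list(primaryids), dtype=object)))
        out = {}
        for name, df in self.tables().items():
            out[name] = df[df["primaryid"].isin(keep)].reset_index(drop=True)
        return RawTables(**out, ground_truth=self.ground_truth,
                         parse_log=dict(self.parse_log))
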