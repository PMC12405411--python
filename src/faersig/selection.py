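"""Primary-suspect case selection and MedDRA PT→SOC term mapping.

A report belongs to the target-drug series when at least one of its DRUG
rows has role code PS (primary suspect) *and* its drug name or active
ingredient matches one of the configured synonyms (e.g. the generic
"laronidase" or the brand "aldurazyme").  Matching is exact-string or
whole-token containment on uppercased names, so "ALDURAZYME (LARONIDASE)"
matches while accidental substrings do not.

MedDRA itself is licensed and not bundled: the PT→SOC mapping is a
user-supplied two-column TSV.  PTs absent from the mapping are bucketed
under the sentinel SOC "UNMAPPED" and counted in the run log.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .errors import ConfigError, FormatError
from .tables import RawTables
from .io import normalize_age_years

UNMAPPED_SOC = "UNMAPPED"

#: outcome codes ordered most → least serious; a report with several OUTC
#: rows is characterized by its most serious one
OUTCOME_SEVERITY = ("DE", "LT", "DS", "CA", "HO", "OT")


class TermMapping:
    """Case-insensitive PT → SOC lookup (many PTs to one SOC)."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self._map: dict[str, str] = {}
        for pt, soc in pairs:
            self._map[str(pt).strip().upper()] = str(soc).strip()

    @classmethod
    def from_tsv(cls, path) -> "TermMapping":
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"cannot read PT-SOC mapping {path}: {exc}") from exc
        if df.shape[1] < 2:
            raise FormatError(f"{path.name}: mapping needs two columns (pt, soc)")
        return cls(zip(df.iloc[:, 0], df.iloc[:, 1]))

    @classmethod
    def from_catalog(cls, pt_catalog) -> "TermMapping":
        return cls((pt, soc) for pt, soc, _ in pt_catalog)

    def get(self, pt: str) -> Optional[str]:
        return self._map.get(str(pt).strip().upper())

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, pt: str) -> bool:
        return self.get(pt) is not None


@dataclass(frozen=True)
class SafetyReport:
    """One deduplicated case, fully assembled for analysis."""

    primaryid: str
    caseid: str
    is_target_ps: bool
    age_years: Optional[float]
    sex: str
    country: str
    reporter: str
    outcome: str
    year: Optional[int]
    pts: frozenset
    socs: frozenset
    event_dt: Optional[int]
    therapy_start_dt: Optional[int]


@dataclass
class ReportSet:
    """Columnar container for an assembled corpus.

    ``reports`` has one row per deduplicated case; ``terms`` is the
    report×term incidence (one row per distinct (primaryid, pt), with the
    SOC the PT maps to).  Disproportionality and descriptive operations all
    run off these two frames.
    """

    reports: pd.DataFrame
    terms: pd.DataFrame
    log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reports)

    @property
    def n_target(self) -> int:
        return int(self.reports["is_target"].sum())

    def target_reports(self) -> pd.DataFrame:
        return self.reports[self.reports["is_target"]]

    def subset(self, mask: pd.Series) -> "ReportSet":
        reports = self.reports[mask].reset_index(drop=True)
        terms = self.terms[self.terms["primaryid"].isin(reports["primaryid"])]
        return ReportSet(reports=reports, terms=terms.reset_index(drop=True),
                         log=dict(self.log))

    def iter_reports(self) -> Iterator[SafetyReport]:
        by_pid = {pid: grp for pid, grp in self.terms.groupby("primaryid")}
        for row in self.reports.itertuples(index=False):
            grp = by_pid.get(row.primaryid)
            pts = frozenset(grp["pt"]) if grp is not None else frozenset()
            socs = frozenset(grp["soc"]) if grp is not None else frozenset()
            yield SafetyReport(
                primaryid=row.primaryid, caseid=row.caseid,
                is_target_ps=bool(row.is_target),
                age_years=None if pd.isna(row.age_years) else float(row.age_years),
                sex=row.sex, country=row.country, reporter=row.reporter,
                outcome=row.outcome,
                year=None if pd.isna(row.year) else int(row.year),
                pts=pts, socs=socs,
                event_dt=None if pd.isna(row.event_dt) else int(row.event_dt),
                therapy_start_dt=(None if pd.isna(row.start_dt)
                                  else int(row.start_dt)),
            )


def _token_pattern(synonyms: Iterable[str]) -> re.Pattern:
    parts = sorted({s.strip().upper() for s in synonyms if s.strip()})
    if not parts:
        raise ConfigError("drug synonym list is empty")
    alternation = "|".join(re.escape(s) for s in parts)
    # whole-token containment: no letter/digit hugging the match
    return re.compile(rf"(?<![A-Z0-9])(?:{alternation})(?![A-Z0-9])")


def match_drug(drug: pd.DataFrame, synonyms: Iterable[str],
               role: str = "PS") -> set:
    """PRIMARYIDs whose report lists a synonym-matching drug with the given
    role code (PS = primary suspect)."""
    pattern = _token_pattern(synonyms)
    if drug.empty:
        return set()
    rows = drug[drug["role_cod"].astype(str).str.strip().str.upper() == role]
    if rows.empty:
        return set()
    name = rows["drugname"].fillna("").astype(str)
    if "prod_ai" in rows.columns:
        name = name + " " + rows["prod_ai"].fillna("").astype(str)
    hit = name.str.upper().str.contains(pattern)
    return set(rows.loc[hit, "primaryid"])


def assemble_reports(raw: RawTables, mapping: TermMapping,
                     synonyms: Iterable[str]) -> ReportSet:
    """Build one :class:`SafetyReport` row per case from deduplicated raw
    tables: target-PS flag, normalized age, most-serious outcome, earliest
    therapy start, and the report×PT/SOC incidence."""
    demo = raw.demo
    target_pids = match_drug(raw.drug, synonyms)

    age_years, n_unknown_unit = normalize_age_years(demo["age"], demo["age_cod"])

    fda = pd.to_numeric(demo["fda_dt"], errors="coerce")
    year = (fda // 10_000).astype("Int64")

    outc = raw.outc
    if len(outc):
        sev = pd.Categorical(
            outc["outc_cod"].astype(str).str.strip().str.upper(),
            categories=OUTCOME_SEVERITY, ordered=True)
        worst = (outc.assign(_sev=sev).dropna(subset=["_sev"])
                 .sort_values("_sev", kind="mergesort")
                 .drop_duplicates("primaryid", keep="first")
                 .set_index("primaryid")["_sev"].astype(str))
    else:
        worst = pd.Series(dtype=object)

    ther = raw.ther
    if len(ther):
        start = (ther.dropna(subset=["start_dt"])
                 .groupby("primaryid")["start_dt"].min())
    else:
        start = pd.Series(dtype=float)

    reports = pd.DataFrame({
        "primaryid": demo["primaryid"].astype(str),
        "caseid": demo["caseid"].astype(str),
        "is_target": demo["primaryid"].isin(target_pids).to_numpy(),
        "age_years": age_years.to_numpy(),
        "sex": demo["sex"].fillna("").astype(str).str.strip().str.upper(),
        "country": demo["reporter_country"].fillna("").astype(str).str.strip(),
        "reporter": demo["occp_cod"].fillna("").astype(str).str.strip().str.upper(),
        "year": year.to_numpy(dtype=float, na_value=float("nan")),
        "event_dt": pd.to_numeric(demo["event_dt"], errors="coerce").to_numpy(),
    })
    reports["outcome"] = reports["primaryid"].map(worst).fillna("")
    reports["start_dt"] = reports["primaryid"].map(start)

    terms = raw.reac[["primaryid", "pt"]].copy()
    terms["primaryid"] = terms["primaryid"].astype(str)
    terms["pt"] = terms["pt"].astype(str).str.strip().str.upper()
    terms = terms[terms["pt"] != ""].drop_duplicates(["primaryid", "pt"])
    socs = terms["pt"].map(lambda pt: mapping.get(pt) or UNMAPPED_SOC)
    terms = terms.assign(soc=socs).reset_index(drop=True)

    unmapped = sorted(terms.loc[terms["soc"] == UNMAPPED_SOC, "pt"].unique())
    log = {
        "n_reports": len(reports),
        "n_target_reports": int(reports["is_target"].sum()),
        "n_unknown_age_unit": n_unknown_unit,
        "n_unmapped_pts": len(unmapped),
        "unmapped_pts": unmapped,
    }
    return ReportSet(reports=reports, terms=terms, log=log)
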