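"""Descriptive characterization of the target-drug report series.

Covers the report-characteristics table (sex, age group, reporter type,
country, outcome, reporting year — counts and percentages of the full
series), the unknown-age sensitivity re-analysis, and the time-to-onset
(TTO) analysis binning days between therapy start and event date.

Percentages are computed against the full series total and rounded
half-up: one decimal for most categories, two for reporting-year rows and
the TTO fraction — the conventions of published FAERS characteristics
tables.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional

import pandas as pd

from .errors import DataError
from .selection import ReportSet
from .disproportionality import (BcpnnPriors, MethodParams, build_tables,
                                 compute_all, stats_frame)

#: conventional TTO bins in days; None = unbounded
DEFAULT_ONSET_BINS = ((0, 30), (31, 60), (61, 90), (91, 180), (181, 360),
                      (361, None))

REPORTER_LABELS = {
    "CN": "Consumer", "HP": "Health Professional", "MD": "Physician",
    "PH": "Pharmacist", "RN": "Registered Nurse", "": "Unknown",
}
OUTCOME_LABELS = {
    "HO": "Hospitalization", "DE": "Death", "CA": "Congenital Anomaly",
    "LT": "Life threatening", "DS": "Disability", "OT": "Other serious",
    "": "Unknown",
}
AGE_GROUPS = ("<5", "5-18", ">18", "Unknown")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (printed-table convention; banker's rounding
    would flip boundary values)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """100·count/total, rounded half-up to the printed precision."""
    if total <= 0:
        raise DataError("percentage undefined for non-positive total")
    return round_half_up(100.0 * count / total, decimals)


def age_group(age_years: Optional[float]) -> str:
    """Age buckets: <5; 5–18 inclusive at both ends; >18; Unknown."""
    if age_years is None or pd.isna(age_years):
        return "Unknown"
    if age_years < 5:
        return "<5"
    if age_years <= 18:
        return "5-18"
    return ">18"


def summarize_counts(counts: dict, total: int, decimals: int = 1,
                     category: str = "") -> pd.DataFrame:
    """Counts → percentage rows against a fixed total (printed-table math)."""
    return pd.DataFrame(
        [{"category": category, "value": value, "count": n,
          "pct": percentage(n, total, decimals)}
         for value, n in counts.items()])


def characteristics(report_set: ReportSet) -> pd.DataFrame:
    """Per-category counts/percentages of the target-report series.

    One tidy frame with columns category/value/count/pct; every category
    partitions the series (an Unknown bucket catches missing values), so
    counts sum to the total within each category.
    """
    tgt = report_set.target_reports()
    total = len(tgt)
    if total == 0:
        raise DataError("no target reports to characterize")

    blocks = [pd.DataFrame([{"category": "Total", "value": "Case reports",
                             "count": total, "pct": 100.0}])]

    sex = tgt["sex"].map({"F": "Female", "M": "Male"}).fillna("Unknown")
    sex[~tgt["sex"].isin(["F", "M"])] = "Unknown"
    order = ["Female", "Male", "Unknown"]
    counts = {k: int((sex == k).sum()) for k in order}
    blocks.append(summarize_counts(counts, total, 1, "Gender"))

    groups = tgt["age_years"].map(age_group)
    counts = {k: int((groups == k).sum()) for k in AGE_GROUPS}
    blocks.append(summarize_counts(counts, total, 1, "Age (year)"))

    rep = tgt["reporter"].map(REPORTER_LABELS).fillna("Unknown")
    rep_order = list(dict.fromkeys(REPORTER_LABELS.values()))
    counts = {k: int((rep == k).sum()) for k in rep_order}
    blocks.append(summarize_counts(counts, total, 1, "Reporter"))

    country = tgt["country"].where(tgt["country"].isin(["US", "BR"]), "Others")
    labels = {"US": "United States", "BR": "Brazil", "Others": "Others"}
    counts = {labels[k]: int((country == k).sum()) for k in labels}
    blocks.append(summarize_counts(counts, total, 1, "Reporter country"))

    out = tgt["outcome"].map(OUTCOME_LABELS).fillna("Unknown")
    out_order = ["Hospitalization", "Death", "Congenital Anomaly",
                 "Life threatening", "Disability", "Other serious", "Unknown"]
    counts = {k: int((out == k).sum()) for k in out_order}
    blocks.append(summarize_counts(counts, total, 1, "Outcome"))

    years = tgt["year"].dropna().astype(int)
    counts = {str(y): int((years == y).sum()) for y in sorted(years.unique())}
    if counts:
        blocks.append(summarize_counts(counts, total, 2, "Reporting year"))

    return pd.concat(blocks, ignore_index=True)


@dataclass
class OnsetResult:
    records: pd.DataFrame       # primaryid, onset_days, bin
    bin_counts: pd.DataFrame    # bin, count
    pct_over_360: float         # of valid records, two decimals
    n_valid: int
    n_excluded: int             # negative or unparseable onsets


def _bin_label(lo: int, hi: Optional[int]) -> str:
    return f">{lo - 1}" if hi is None else f"{lo}-{hi}"


def onset_analysis(report_set: ReportSet,
                   bins: Iterable[tuple] = DEFAULT_ONSET_BINS) -> OnsetResult:
    """Days from (earliest) therapy start to event date, binned.

    Records with a missing date pair or a negative difference are excluded
    and counted.  The headline fraction is the share of valid records with
    onset beyond 360 days.
    """
    bins = tuple(bins)
    tgt = report_set.target_reports()
    have = tgt.dropna(subset=["start_dt", "event_dt"])
    start = pd.to_datetime(have["start_dt"].astype("int64").astype(str),
                           format="%Y%m%d", errors="coerce")
    event = pd.to_datetime(have["event_dt"].astype("int64").astype(str),
                           format="%Y%m%d", errors="coerce")
    onset = (event - start).dt.days
    valid = onset.notna() & (onset >= 0)
    n_excluded = int((~valid).sum())
    records = pd.DataFrame({
        "primaryid": have.loc[valid, "primaryid"].to_numpy(),
        "onset_days": onset[valid].astype(int).to_numpy(),
    })

    labels = [_bin_label(lo, hi) for lo, hi in bins]

    def assign(days: int) -> str:
        for (lo, hi), label in zip(bins, labels):
            if days >= lo and (hi is None or days <= hi):
                return label
        return labels[-1]

    records["bin"] = records["onset_days"].map(assign)
    bin_counts = pd.DataFrame({
        "bin": labels,
        "count": [int((records["bin"] == lab).sum()) for lab in labels],
    })
    n_valid = len(records)
    pct = (percentage(int((records["onset_days"] > 360).sum()), n_valid, 2)
           if n_valid else float("nan"))
    return OnsetResult(records=records, bin_counts=bin_counts,
                       pct_over_360=pct, n_valid=n_valid,
                       n_excluded=n_excluded)


@dataclass
class SensitivityResult:
    compare: pd.DataFrame       # rank, term, a_full, a_subset per top list
    subset_stats: pd.DataFrame
    n_excluded: int


def sensitivity_exclude_unknown_age(report_set: ReportSet, top_n: int = 20,
                                    level: str = "pt",
                                    priors: BcpnnPriors = BcpnnPriors(),
                                    params: MethodParams = MethodParams()
                                    ) -> SensitivityResult:
    """Re-run the disproportionality analysis on age-known reports only and
    compare the frequency-ranked top terms with the full-series ranking."""
    known = report_set.reports["age_years"].notna()
    n_excluded = int((~known).sum())
    subset = report_set.subset(known)
    if len(subset) == 0 or subset.n_target == 0:
        raise DataError("sensitivity subset is empty: every report (or every "
                        "target report) lacks age information")

    def top_frame(rs: ReportSet) -> pd.DataFrame:
        stats = compute_all(build_tables(rs, level), level, priors, params)
        df = stats_frame(stats)
        df = df[df["estimable"]].sort_values(["a", "term"],
                                             ascending=[False, True])
        return df.head(top_n).reset_index(drop=True)

    full = top_frame(report_set)
    sub = top_frame(subset)
    compare = pd.DataFrame({
        "rank": range(1, max(len(full), len(sub)) + 1),
    })
    compare["term_full"] = pd.Series(full["term"])
    compare["a_full"] = pd.Series(full["a"])
    compare["term_subset"] = pd.Series(sub["term"])
    compare["a_subset"] = pd.Series(sub["a"])
    subset_stats = stats_frame(
        compute_all(build_tables(subset, level), level, priors, params))
    return SensitivityResult(compare=compare, subset_stats=subset_stats,
                             n_excluded=n_excluded)
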