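"""End-to-end orchestration: read → dedup → select → tables → statistics →
screen → descriptives → onset, with a JSON run manifest of stage counts."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .tables import RawTables
from .io import dedup_tables
from .selection import TermMapping, ReportSet, assemble_reports
from .disproportionality import (BcpnnPriors, MethodParams, build_tables,
                                 compute_all, stats_frame)
from .screen import ScreenResult, screen, soc_summary, venn_frame, \
    format_top_table, forest_frame
from .descriptives import (OnsetResult, SensitivityResult, characteristics,
                           onset_analysis, sensitivity_exclude_unknown_age,
                           DEFAULT_ONSET_BINS)
from .errors import DataError


@dataclass
class AnalysisResult:
    report_set: ReportSet
    stats_pt: pd.DataFrame
    screen_pt: ScreenResult
    stats_soc: Optional[pd.DataFrame]
    soc_table: Optional[pd.DataFrame]
    characteristics: pd.DataFrame
    onset: OnsetResult
    sensitivity: Optional[SensitivityResult]
    manifest: dict = field(default_factory=dict)


def analyze(raw: RawTables, mapping: TermMapping, synonyms: Iterable[str],
            level: str = "both", top_n: int = 20,
            onset_bins: Iterable[tuple] = DEFAULT_ONSET_BINS,
            priors: BcpnnPriors = BcpnnPriors(),
            params: MethodParams = MethodParams(),
            run_sensitivity: bool = True,
            exclude_unknown_age: bool = False) -> AnalysisResult:
    """Run the whole analysis on raw (not yet deduplicated) tables.

    With ``exclude_unknown_age`` the whole analysis is restricted to
    age-known reports (the sensitivity comparison, when enabled, still
    contrasts the analyzed corpus against its age-known subset).
    """
    if raw.demo.empty:
        raise DataError("no reports in input: DEMO table is empty")
    manifest = {"raw_rows": raw.n_rows(),
                "parse_log": dict(raw.parse_log)}

    clean = dedup_tables(raw)
    manifest["n_raw_report_versions"] = len(raw.demo)
    manifest["n_deduplicated_cases"] = len(clean.demo)

    rs = assemble_reports(clean, mapping, synonyms)
    if exclude_unknown_age:
        rs = rs.subset(rs.reports["age_years"].notna())
        manifest["n_age_known_cases"] = len(rs)
        if len(rs) == 0:
            raise DataError("every report lacks age information")
    manifest["n_target_reports"] = rs.n_target
    manifest["n_unmapped_pts"] = rs.log["n_unmapped_pts"]
    if rs.n_target == 0:
        raise DataError("no reports with the target drug as primary suspect")

    # PT statistics are always computed (the screen runs off them); SOC is
    # optional per `level`
    do_soc = level in ("soc", "both")
    stats_pt_list = compute_all(build_tables(rs, "pt"), "pt", priors, params)
    screen_pt = screen(stats_pt_list, top_n=top_n)
    manifest["n_pt_terms"] = len(stats_pt_list)
    manifest["n_pt_estimable"] = sum(s.estimable for s in stats_pt_list)
    manifest["n_pt_final_signals"] = screen_pt.n_final

    stats_soc = soc_table = None
    if do_soc:
        stats_soc_list = compute_all(build_tables(rs, "soc"), "soc",
                                     priors, params)
        stats_soc = stats_frame(stats_soc_list).rename(columns={"term": "soc"})
        soc_table = soc_summary(stats_soc_list)
        manifest["n_soc_terms"] = len(stats_soc_list)

    chars = characteristics(rs)
    onset = onset_analysis(rs, onset_bins)
    manifest["n_onset_valid"] = onset.n_valid
    manifest["n_onset_excluded"] = onset.n_excluded

    sensitivity = None
    if run_sensitivity:
        try:
            sensitivity = sensitivity_exclude_unknown_age(
                rs, top_n=top_n, priors=priors, params=params)
            manifest["n_age_unknown_excluded"] = sensitivity.n_excluded
        except DataError:
            manifest["n_age_unknown_excluded"] = len(rs)

    return AnalysisResult(
        report_set=rs, stats_pt=stats_frame(stats_pt_list), screen_pt=screen_pt,
        stats_soc=stats_soc, soc_table=soc_table, characteristics=chars,
        onset=onset, sensitivity=sensitivity, manifest=manifest)


def write_results(result: AnalysisResult, outdir,
                  mapping: Optional[TermMapping] = None) -> None:
    """Persist all result tables as TSV plus the run manifest as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(outdir / name, sep="\t", index=False)

    tsv(result.stats_pt, "signals_pt.tsv")
    tsv(venn_frame(result.screen_pt), "venn_counts.tsv")
    tsv(format_top_table(result.screen_pt, mapping), "top20_pt.tsv")
    tsv(forest_frame(result.screen_pt.stats), "forest_pt.tsv")
    pd.DataFrame({"pt": result.screen_pt.final_signals}).to_csv(
        outdir / "final_signals_pt.tsv", sep="\t", index=False)
    if result.stats_soc is not None:
        tsv(result.stats_soc, "signals_soc.tsv")
        tsv(result.soc_table, "soc_summary.tsv")
    tsv(result.characteristics, "characteristics.tsv")
    tsv(result.onset.bin_counts, "onset_bins.tsv")
    tsv(result.onset.records, "onset_records.tsv")
    if result.sensitivity is not None:
        tsv(result.sensitivity.compare, "sensitivity_compare.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
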