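"""Joint four-algorithm screening: intersection signals, Venn regions,
per-SOC summary and frequency-ranked top-N tables.

High-sensitivity methods (ROR, PRR) and high-specificity methods (the
Bayesian IC and the O/E-based EBGM bound) are combined conservatively: a
term is a *final* signal only when it passes all four criteria.  The
exclusive Venn region counts describe how the algorithms disagree.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import pandas as pd

from .disproportionality import SignalStats, stats_frame
from .selection import TermMapping

ALGORITHMS = ("ROR", "PRR", "EBGM", "BCPNN")

#: the 15 non-empty algorithm subsets, in canonical order
VENN_REGIONS = tuple(
    "&".join(combo)
    for size in range(1, len(ALGORITHMS) + 1)
    for combo in combinations(ALGORITHMS, size)
)


@dataclass
class ScreenResult:
    stats: list                 # SignalStats, input order
    final_signals: list         # terms passing all four, sorted
    venn_counts: dict           # exclusive region -> term count
    top: pd.DataFrame           # top-N by report count a

    @property
    def n_final(self) -> int:
        return len(self.final_signals)


def _region(s: SignalStats) -> Optional[str]:
    names = [alg for alg in ALGORITHMS if s.flags[alg]]
    return "&".join(names) if names else None


def screen(stats: Iterable[SignalStats], top_n: int = 20) -> ScreenResult:
    """Intersect the four flag sets and rank terms by reporting frequency.

    Venn regions are exclusive (a term lands in exactly the subset of
    algorithms that flag it), so the region counts sum to the union size.
    The top-N list ranks estimable terms by ``a`` descending, ties broken
    lexicographically by term.
    """
    stats = list(stats)
    venn = {region: 0 for region in VENN_REGIONS}
    final = []
    for s in stats:
        region = _region(s)
        if region is not None:
            venn[region] += 1
        if all(s.flags.values()):
            final.append(s.term)

    ranked = sorted((s for s in stats if s.estimable),
                    key=lambda s: (-s.a, s.term))
    top = stats_frame(ranked[:top_n])
    return ScreenResult(stats=stats, final_signals=sorted(final),
                        venn_counts=venn, top=top)


def soc_summary(stats: Iterable[SignalStats]) -> pd.DataFrame:
    """One row per SOC with cells, ROR and CI, and all flags, sorted by ROR
    descending (non-estimable SOCs last)."""
    df = stats_frame(stats)
    df = df.rename(columns={"term": "soc"})
    return (df.sort_values(["ror", "soc"], ascending=[False, True],
                           na_position="last")
            .reset_index(drop=True))


def venn_frame(result: ScreenResult) -> pd.DataFrame:
    return pd.DataFrame(
        {"algorithms": list(result.venn_counts),
         "n_terms": list(result.venn_counts.values())})


def _fmt(x: float, nd: int = 2) -> str:
    return "NA" if pd.isna(x) else f"{x:.{nd}f}"


def format_top_table(result: ScreenResult,
                     mapping: Optional[TermMapping] = None) -> pd.DataFrame:
    """Publication-style layout of the top-N list: SOC, PT, case number,
    'ROR (95% CI)', 'IC (IC025)', 'PRR (chi2)', 'EBGM (EBGM05)'."""
    rows = []
    for r in result.top.itertuples(index=False):
        soc = mapping.get(r.term) if mapping is not None else None
        rows.append({
            "soc": soc or "",
            "pt": r.term,
            "case_number": r.a,
            "ror_95ci": f"{_fmt(r.ror)} ({_fmt(r.ror_ci_low)}-{_fmt(r.ror_ci_high)})",
            "ic_ic025": f"{_fmt(r.ic)} ({_fmt(r.ic025)})",
            "prr_chi2": f"{_fmt(r.prr)} ({_fmt(r.chi2)})",
            "ebgm_ebgm05": f"{_fmt(r.ebgm)} ({_fmt(r.ebgm05)})",
        })
    return pd.DataFrame(rows, columns=["soc", "pt", "case_number", "ror_95ci",
                                       "ic_ic025", "prr_chi2", "ebgm_ebgm05"])


def forest_frame(stats: Iterable[SignalStats]) -> pd.DataFrame:
    """Forest-plot-ready slice: term, ROR with CI bounds, report count."""
    df = stats_frame(stats)
    return df.loc[df["estimable"],
                  ["term", "ror", "ror_ci_low", "ror_ci_high", "a"]
                  ].reset_index(drop=True)
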