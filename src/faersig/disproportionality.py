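"""2×2 contingency tables and the four disproportionality algorithms.

For a target drug and one adverse-event term (a MedDRA PT, or its SOC), the
classical pharmacovigilance 2×2 table over the report×term incidence is

    =============  ============  ============
                   target term   other terms
    target drug         a             b
    other drugs         c             d
    =============  ============  ============

with N = a + b + c + d.  The four frequentist/Bayesian statistics computed
here, with their conventional signal criteria, are:

* **ROR** (reporting odds ratio) = ad/bc, signal when a ≥ 3 and the lower
  95% CI bound exp(ln ROR − 1.96·√(1/a+1/b+1/c+1/d)) exceeds 1;
* **PRR** (proportional reporting ratio) = [a/(a+b)]/[c/(c+d)], signal when
  a ≥ 3, PRR ≥ 2 and the (uncorrected) χ² = (ad−bc)²N/[(a+b)(a+c)(c+d)(b+d)]
  is ≥ 4;
* **EBGM**, here the observed/expected reporting ratio aN/[(a+b)(a+c)] with
  one-sided lower bound EBGM05 = exp(ln EBGM − 1.64·√(1/a+1/b+1/c+1/d)),
  signal when EBGM05 > 2 (note this is the plain O/E ratio, not the full
  Gamma–Poisson mixture fit — see the methods note);
* **BCPNN**: the information component IC = log₂(aN/[(a+b)(a+c)]) with the
  Bayesian posterior mean E(IC) and variance V(IC) under unit Dirichlet-style
  hyperparameters (α₁=α₂=β₁=β₂=γ₁₁=1), signal when a ≥ 3 and the credibility
  lower bound IC025 = E(IC) − 1.96·√V(IC) exceeds 0.

IC and log₂(EBGM) coincide identically — both are the log₂ observed/expected
ratio — and on any table ROR ≥ PRR ≥ EBGM when ad > bc.

Counting unit: a report contributes at most once per term; b and d count
report–term pairs over the same term universe at the same level, so N is
the total number of report–term incidences at that level and is constant
across terms.  Tables with a zero in any required denominator are marked
non-estimable (no continuity correction is applied) and never flagged.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable

import pandas as pd

from .errors import DataError
from .selection import ReportSet

LEVELS = ("pt", "soc")
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts for one (drug, term) pair; all cells non-negative, N > 0."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("contingency cells must be non-negative")
        if self.n == 0:
            raise DataError("contingency table is empty (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def estimable(self) -> bool:
        """All four statistics (and both interval bounds) are finite only
        when every cell is positive."""
        return min(self.a, self.b, self.c, self.d) > 0


@dataclass(frozen=True)
class BcpnnPriors:
    """Hyperparameters of the BCPNN posterior; the conventional choice sets
    every elementary parameter to 1 (so alpha = beta = 2)."""

    alpha1: float = 1.0
    alpha2: float = 1.0
    beta1: float = 1.0
    beta2: float = 1.0
    gamma11: float = 1.0

    def __post_init__(self):
        if min(self.alpha1, self.alpha2, self.beta1, self.beta2, self.gamma11) <= 0:
            raise DataError("BCPNN priors must be strictly positive")

    @property
    def alpha(self) -> float:
        return self.alpha1 + self.alpha2

    @property
    def beta(self) -> float:
        return self.beta1 + self.beta2


@dataclass(frozen=True)
class MethodParams:
    """Fixed constants of the four algorithms and their signal criteria."""

    z_two_sided: float = 1.96   # ROR 95% CI, IC credibility interval
    z_one_sided: float = 1.64   # EBGM05 lower bound
    a_min: int = 3
    ror_ci_low_min: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ebgm05_min: float = 2.0
    ic025_min: float = 0.0


@dataclass
class SignalStats:
    """All per-term statistics, interval bounds and per-algorithm flags."""

    term: str
    level: str
    a: int
    b: int
    c: int
    d: int
    estimable: bool
    ror: float = math.nan
    ror_ci_low: float = math.nan
    ror_ci_high: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    ic: float = math.nan
    eic: float = math.nan
    vic: float = math.nan
    ic025: float = math.nan
    ic975: float = math.nan
    ror_signal: bool = False
    prr_signal: bool = False
    ebgm_signal: bool = False
    bcpnn_signal: bool = False

    @property
    def flags(self) -> dict[str, bool]:
        return {"ROR": self.ror_signal, "PRR": self.prr_signal,
                "EBGM": self.ebgm_signal, "BCPNN": self.bcpnn_signal}


def build_tables(report_set: ReportSet, level: str = "pt"
                 ) -> dict[str, ContingencyTable]:
    """One table per distinct term observed anywhere in the corpus.

    ``a`` counts target-drug reports containing the term at least once; at
    SOC level a report counts once per SOC no matter how many of its PTs
    map there.  N (total report–term incidences at the level) is identical
    across the returned tables.
    """
    if level not in LEVELS:
        raise DataError(f"level must be one of {LEVELS}, got {level!r}")
    if len(report_set) == 0:
        raise DataError("empty corpus: no reports to tabulate")
    pairs = report_set.terms[["primaryid", level]].drop_duplicates()
    if pairs.empty:
        raise DataError("empty corpus: no report-term incidences")
    is_target = report_set.reports.set_index("primaryid")["is_target"]
    flagged = pairs[level].groupby(
        is_target.reindex(pairs["primaryid"]).to_numpy())
    counts_by_side = {side: grp.value_counts() for side, grp in flagged}
    a_counts = counts_by_side.get(True, pd.Series(dtype=int))
    c_counts = counts_by_side.get(False, pd.Series(dtype=int))
    target_pairs = int(a_counts.sum())
    other_pairs = int(c_counts.sum())

    tables: dict[str, ContingencyTable] = {}
    for term in sorted(pairs[level].unique()):
        a = int(a_counts.get(term, 0))
        c = int(c_counts.get(term, 0))
        tables[term] = ContingencyTable(
            a=a, b=target_pairs - a, c=c, d=other_pairs - c)
    return tables


def compute_ror(t: ContingencyTable, p: MethodParams = MethodParams()
                ) -> tuple[float, float, float]:
    """ROR = ad/bc with Woolf 95% CI on the log scale; NaNs on a zero cell."""
    if min(t.a, t.b, t.c, t.d) <= 0:
        return math.nan, math.nan, math.nan
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (ror, math.exp(math.log(ror) - p.z_two_sided * se),
            math.exp(math.log(ror) + p.z_two_sided * se))


def compute_prr(t: ContingencyTable, p: MethodParams = MethodParams()
                ) -> tuple[float, float]:
    """PRR and the uncorrected chi-squared statistic of the table."""
    if t.a + t.b == 0 or t.c == 0 or t.c + t.d == 0:
        return math.nan, math.nan
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    margins = (t.a + t.b) * (t.a + t.c) * (t.c + t.d) * (t.b + t.d)
    chi2 = ((t.a * t.d - t.b * t.c) ** 2) * t.n / margins if margins else math.nan
    return prr, chi2


def compute_ebgm(t: ContingencyTable, p: MethodParams = MethodParams()
                 ) -> tuple[float, float]:
    """Observed/expected ratio aN/[(a+b)(a+c)] and its one-sided (z=1.64)
    lower bound; the bound needs every cell positive."""
    if t.a == 0 or t.a + t.b == 0 or t.a + t.c == 0:
        return math.nan, math.nan
    ebgm = t.a * t.n / ((t.a + t.b) * (t.a + t.c))
    if min(t.b, t.c, t.d) <= 0:
        return ebgm, math.nan
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return ebgm, math.exp(math.log(ebgm) - p.z_one_sided * se)


def compute_bcpnn(t: ContingencyTable, priors: BcpnnPriors = BcpnnPriors(),
                  p: MethodParams = MethodParams()
                  ) -> tuple[float, float, float, float, float]:
    """IC, E(IC), V(IC) and the credibility bounds IC025/IC975.

    E(IC) and V(IC) are defined even when a = 0 (the posterior shrinks the
    estimate toward independence); the point IC itself needs a > 0.
    """
    n = t.n
    a1, b1, g11 = priors.alpha1, priors.beta1, priors.gamma11
    alpha, beta = priors.alpha, priors.beta
    row = t.a + t.b + a1
    col = t.a + t.c + b1
    if row <= 0 or col <= 0:
        return (math.nan,) * 5
    if t.a > 0 and t.a + t.b > 0 and t.a + t.c > 0:
        ic = math.log2(t.a * n / ((t.a + t.b) * (t.a + t.c)))
    else:
        ic = math.nan
    gamma = g11 * (n + alpha) * (n + beta) / (row * col)
    eic = math.log2((t.a + g11) * (n + alpha) * (n + beta)
                    / ((n + gamma) * row * col))
    vic = (1.0 / (_LN2 ** 2)) * (
        (n - t.a + gamma - g11) / ((t.a + g11) * (n + 1 + gamma))
        + (n - t.a - t.b + alpha - a1) / (row * (n + 1 + alpha))
        + (n - t.a - t.c + beta - b1) / (col * (n + 1 + beta)))
    half = p.z_two_sided * math.sqrt(vic)
    return ic, eic, vic, eic - half, eic + half


def evaluate_criteria(s: SignalStats, p: MethodParams = MethodParams()
                      ) -> dict[str, bool]:
    """Apply the four decision rules; a non-estimable table never signals."""
    if not s.estimable:
        return {"ROR": False, "PRR": False, "EBGM": False, "BCPNN": False}
    return {
        "ROR": s.a >= p.a_min and s.ror_ci_low > p.ror_ci_low_min,
        "PRR": (s.a >= p.a_min and s.prr >= p.prr_min and s.chi2 >= p.chi2_min),
        "EBGM": s.ebgm05 > p.ebgm05_min,
        "BCPNN": s.a >= p.a_min and s.ic025 > p.ic025_min,
    }


def compute_stats(term: str, t: ContingencyTable, level: str = "pt",
                  priors: BcpnnPriors = BcpnnPriors(),
                  params: MethodParams = MethodParams()) -> SignalStats:
    """All Table-style statistics and flags for one term."""
    s = SignalStats(term=term, level=level, a=t.a, b=t.b, c=t.c, d=t.d,
                    estimable=t.estimable)
    s.ror, s.ror_ci_low, s.ror_ci_high = compute_ror(t, params)
    s.prr, s.chi2 = compute_prr(t, params)
    s.ebgm, s.ebgm05 = compute_ebgm(t, params)
    s.ic, s.eic, s.vic, s.ic025, s.ic975 = compute_bcpnn(t, priors, params)
    flags = evaluate_criteria(s, params)
    s.ror_signal, s.prr_signal = flags["ROR"], flags["PRR"]
    s.ebgm_signal, s.bcpnn_signal = flags["EBGM"], flags["BCPNN"]
    return s


def compute_all(tables: dict[str, ContingencyTable], level: str = "pt",
                priors: BcpnnPriors = BcpnnPriors(),
                params: MethodParams = MethodParams()) -> list[SignalStats]:
    return [compute_stats(term, t, level, priors, params)
            for term, t in tables.items()]


def stats_frame(stats: Iterable[SignalStats]) -> pd.DataFrame:
    """Flatten SignalStats into a tidy one-row-per-term DataFrame."""
    cols = [f.name for f in dc_fields(SignalStats)]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in stats],
                        columns=cols)
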