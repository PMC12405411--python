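"""Contingency construction and the four algorithms: hand-checked values,
analytic nulls, structural identities and oracle equivalence."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import faersig as fs
from faersig.disproportionality import (compute_bcpnn, compute_ebgm,
                                        compute_prr, compute_ror)
from tests.oracle import oracle_stats

T = fs.ContingencyTable

cells = st.integers(1, 10 ** 6)


def reportset_from(specs) -> fs.ReportSet:
    """Build a ReportSet from (is_target, pts) pairs; SOC = 'S:'+pt."""
    reports = pd.DataFrame({
        "primaryid": [str(i) for i in range(len(specs))],
        "caseid": [str(i) for i in range(len(specs))],
        "is_target": [t for t, _ in specs],
        "age_years": np.nan, "sex": "", "country": "", "reporter": "",
        "year": np.nan, "event_dt": np.nan, "outcome": "", "start_dt": np.nan,
    })
    rows = [(str(i), pt, f"S:{pt}")
            for i, (_, pts) in enumerate(specs) for pt in pts]
    terms = pd.DataFrame(rows, columns=["primaryid", "pt", "soc"])
    return fs.ReportSet(reports=reports, terms=terms)


# ------------------------------------------------------------ build_tables

def test_four_report_corpus_by_hand():
    rs = reportset_from([
        (True, ["X"]), (True, ["Y"]), (False, ["X"]), (False, ["Y"]),
    ])
    t = fs.build_tables(rs, "pt")["X"]
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)


def test_term_only_in_comparators_has_zero_a():
    rs = reportset_from([(True, ["Y"]), (False, ["X", "Y"])])
    t = fs.build_tables(rs, "pt")["X"]
    assert t.a == 0 and not t.estimable


def test_n_constant_across_terms(study_reports):
    tables = fs.build_tables(study_reports, "pt")
    ns = {t.n for t in tables.values()}
    assert len(ns) == 1
    # N = total report-term incidences at PT level
    assert ns.pop() == len(
        study_reports.terms[["primaryid", "pt"]].drop_duplicates())


def test_planted_a_matches_ledger_recount(nodup_reports, nodup_raw):
    """a for a planted PT equals the generator's direct target-report count
    (exact when duplicate_rate=0)."""
    tables = fs.build_tables(nodup_reports, "pt")
    ledger = nodup_raw.ground_truth.planted_target_counts
    for row in ledger.itertuples(index=False):
        assert tables[row.pt].a == row.n_target_reports_with_pt


def test_soc_level_counts_once_per_report_per_soc(nodup_reports):
    tables = fs.build_tables(nodup_reports, "soc")
    # brute-force recount with python sets
    tgt = set(nodup_reports.reports.loc[
        nodup_reports.reports["is_target"], "primaryid"])
    by_soc: dict[str, set] = {}
    for row in nodup_reports.terms.itertuples(index=False):
        by_soc.setdefault(row.soc, set()).add(row.primaryid)
    for soc, pids in by_soc.items():
        assert tables[soc].a == len(pids & tgt)


def test_empty_corpus_raises():
    rs = reportset_from([])
    with pytest.raises(fs.DataError):
        fs.build_tables(rs, "pt")


# ----------------------------------------------------------- hand values

def test_symmetric_unit_table():
    t = T(1, 1, 1, 1)
    ror, lo, hi = compute_ror(t)
    assert ror == pytest.approx(1.0, abs=1e-15)
    assert lo == pytest.approx(math.exp(-3.92), rel=1e-12)
    assert hi == pytest.approx(math.exp(3.92), rel=1e-12)
    prr, chi2 = compute_prr(t)
    assert prr == 1.0 and chi2 == 0.0
    ebgm, _ = compute_ebgm(t)
    assert ebgm == 1.0
    ic, eic, vic, ic025, ic975 = compute_bcpnn(t)
    assert ic == 0.0 and eic == pytest.approx(0.0, abs=1e-15)
    o = oracle_stats(1, 1, 1, 1)
    assert vic == pytest.approx(o["vic"], rel=1e-10)
    assert ic025 == pytest.approx(o["ic025"], rel=1e-10)


def test_three_one_one_three_table():
    t = T(3, 1, 1, 3)
    ror, _, _ = compute_ror(t)
    assert ror == 9.0
    prr, chi2 = compute_prr(t)
    assert prr == 3.0 and chi2 == 2.0
    ebgm, _ = compute_ebgm(t)
    assert ebgm == 1.5


def test_gamma_equals_four_on_symmetric_table():
    # the symmetric unit table makes the BCPNN shrinkage prior gamma = 4
    o = oracle_stats(1, 1, 1, 1)
    assert o["eic"] == pytest.approx(0.0, abs=1e-15)


# ----------------------------------------------------- zero-cell handling

@pytest.mark.parametrize("table", [(0, 5, 3, 9), (4, 0, 3, 9), (4, 5, 0, 9)])
def test_zero_cells_yield_non_estimable_not_exceptions(table):
    s = fs.compute_stats("X", T(*table))
    assert not s.estimable
    assert not any(s.flags.values())
    assert math.isnan(s.ror)


def test_bcpnn_posterior_defined_at_a_zero():
    ic, eic, vic, ic025, _ = compute_bcpnn(T(0, 5, 3, 9))
    assert math.isnan(ic)          # point IC needs a > 0
    assert math.isfinite(eic) and math.isfinite(vic)
    assert ic025 < 0               # shrunk well below independence


def test_negative_cells_rejected():
    with pytest.raises(fs.DataError):
        T(-1, 1, 1, 1)


# ------------------------------------------------------------- criteria

def test_a_below_three_never_signals():
    s = fs.compute_stats("X", T(2, 1, 1, 10 ** 6))  # huge ROR, a=2
    assert s.ror > 100
    assert not s.ror_signal and not s.prr_signal and not s.bcpnn_signal


def test_frequent_term_with_high_ci_low_signals():
    # a=465-style term: CI lower bound far above 1 → ROR criterion fires
    s = fs.compute_stats("PYREXIA", T(465, 3212, 80_000, 1_000_000))
    assert s.a >= 3 and s.ror_ci_low > 1
    assert s.ror_signal


def test_null_table_all_flags_false():
    s = fs.compute_stats("X", T(1, 1, 1, 1))
    assert not any(s.flags.values())


# ------------------------------------------------- structural identities

@given(a=cells, b=cells, c=cells, d=cells)
def test_ic_equals_log2_ebgm(a, b, c, d):
    t = T(a, b, c, d)
    ebgm, _ = compute_ebgm(t)
    ic = compute_bcpnn(t)[0]
    assert ic == pytest.approx(math.log2(ebgm), abs=1e-12)


@given(a=cells, b=cells, c=cells, d=cells)
def test_ordering_ror_ge_prr_ge_ebgm(a, b, c, d):
    t = T(a, b, c, d)
    ror = compute_ror(t)[0]
    prr = compute_prr(t)[0]
    ebgm = compute_ebgm(t)[0]
    if a * d > b * c:
        assert ror >= prr * (1 - 1e-12) and prr >= ebgm * (1 - 1e-12)
    elif a * d == b * c:
        assert ror == pytest.approx(prr, rel=1e-12)
        assert prr == pytest.approx(ebgm, rel=1e-12)


@pytest.mark.parametrize("base", [(3, 1, 1, 3), (10, 90, 100, 9800),
                                  (5, 2, 7, 100)])
def test_shrinkage_vanishes_with_scale(base):
    """E(IC) < IC when ad > bc, and the gap shrinks monotonically as the
    table is scaled up."""
    a, b, c, d = base
    assert a * d > b * c
    gaps = []
    for m in (1, 2, 4, 8):
        t = T(a * m, b * m, c * m, d * m)
        ic, eic = compute_bcpnn(t)[0], compute_bcpnn(t)[1]
        assert eic < ic
        gaps.append(ic - eic)
    assert gaps == sorted(gaps, reverse=True)
    big = T(a * 1000, b * 1000, c * 1000, d * 1000)
    ic, eic = compute_bcpnn(big)[0], compute_bcpnn(big)[1]
    assert abs(ic - eic) < 0.01


def test_large_n_limit_eic_close_to_ic():
    # oracle-computed gap for this table: 0.011881389340590687
    t = T(1000, 9000, 10_000, 980_000)
    ic, eic = compute_bcpnn(t)[0], compute_bcpnn(t)[1]
    o = oracle_stats(1000, 9000, 10_000, 980_000)
    assert abs((ic - eic) - (o["ic"] - o["eic"])) < 1e-10
    assert abs(eic - ic) < 0.02    # shrinkage already nearly negligible


def test_ror_prr_strictly_increase_in_a():
    rors, prrs = [], []
    for a in range(1, 40):
        t = T(a, 7, 11, 900)
        rors.append(compute_ror(t)[0])
        prrs.append(compute_prr(t)[0])
    assert all(x < y for x, y in zip(rors, rors[1:]))
    assert all(x < y for x, y in zip(prrs, prrs[1:]))


def test_ebgm_saturates_in_a():
    """The O/E ratio is NOT monotone in a (N grows with a): it rises, then
    decays toward 1 — the documented behavior of the printed formula."""
    f = lambda a: compute_ebgm(T(a, 1, 1, 1))[0]
    assert f(3) > f(10) > f(100)
    assert f(10 ** 6) == pytest.approx(1.0, abs=1e-4)


# -------------------------------------------------------- oracle (small)

@given(a=cells, b=cells, c=cells, d=cells)
def test_matches_independent_oracle(a, b, c, d):
    s = fs.compute_stats("X", T(a, b, c, d))
    o = oracle_stats(a, b, c, d)
    for key, want in o.items():
        got = getattr(s, key)
        assert math.isclose(got, want, rel_tol=1e-10, abs_tol=1e-12), key


def test_stats_frame_layout(study_reports):
    stats = fs.compute_all(fs.build_tables(study_reports, "pt"), "pt")
    df = fs.stats_frame(stats)
    assert {"term", "a", "ror", "prr", "ebgm", "ic025", "ror_signal"} <= \
        set(df.columns)
    assert len(df) == len(stats)
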