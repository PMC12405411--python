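"""Generator contracts: determinism, planted-signal calibration, duplicate
and missingness structure."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import faersig as fs
from faersig.config import PLANTED_PTS

PLANTED = [pt for pt, _ in PLANTED_PTS]


def test_empty_corpus_yields_empty_tables():
    raw = fs.generate_dataset(fs.SimulationConfig(n_reports=0, seed=3))
    assert all(n == 0 for n in raw.n_rows().values())
    assert raw.ground_truth.n_logical_cases == 0


def test_same_seed_is_byte_identical(tmp_path):
    cfg = fs.SimulationConfig(n_reports=1500, seed=42)
    fs.write_dataset(cfg, tmp_path / "a", dialect="ascii")
    fs.write_dataset(cfg, tmp_path / "b", dialect="ascii")
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_different_seeds_differ():
    r1 = fs.generate_dataset(fs.SimulationConfig(n_reports=500, seed=1))
    r2 = fs.generate_dataset(fs.SimulationConfig(n_reports=500, seed=2))
    assert not r1.reac.equals(r2.reac)


def test_planted_pt_count_matches_binomial_expectation():
    """Target-drug reports carrying a planted PT (q=0.02, RR=8): the count
    is Binomial(n, p_target·0.16); direct recount from the raw tables must
    fall within 3 binomial standard deviations of 20000·0.01·0.16."""
    cfg = fs.SimulationConfig(seed=1)  # n=20000, p_target=0.01
    raw = fs.generate_dataset(cfg)
    # independent recount: version-1 rows only, PS drug name in synonyms
    demo1 = raw.demo[raw.demo["caseversion"] == 1]
    ps = raw.drug[(raw.drug["role_cod"] == "PS")
                  & raw.drug["drugname"].isin(cfg.target_drug_synonyms)]
    target_pids = set(ps["primaryid"]) & set(demo1["primaryid"])
    reac1 = raw.reac[raw.reac["primaryid"].isin(target_pids)]
    p = cfg.p_target * min(1.0, 0.02 * 8)
    mean = cfg.n_reports * p
    sd = math.sqrt(cfg.n_reports * p * (1 - p))
    for pt in PLANTED:
        count = reac1.loc[reac1["pt"] == pt, "primaryid"].nunique()
        assert abs(count - mean) <= 3 * sd
        # and the generator's own ledger agrees with the recount
        ledger = raw.ground_truth.planted_target_counts
        assert int(ledger.loc[ledger["pt"] == pt,
                              "n_target_reports_with_pt"].iloc[0]) == count


def test_empirical_relative_risk_converges(study_config):
    """At n=50,000 the empirical reporting-rate ratio of a planted PT lies
    within a 3-SE delta-method band around the configured RR=8."""
    cfg = fs.SimulationConfig(n_reports=50_000, seed=9)
    raw = fs.generate_dataset(cfg)
    truth = raw.ground_truth
    demo1 = raw.demo[raw.demo["caseversion"] == 1]
    tgt_cases = set(truth.cases.loc[truth.cases["is_target"], "caseid"])
    is_tgt = demo1["caseid"].isin(tgt_cases)
    tgt_pids = set(demo1.loc[is_tgt, "primaryid"])
    oth_pids = set(demo1.loc[~is_tgt, "primaryid"])
    reac1 = raw.reac[raw.reac["primaryid"].isin(set(demo1["primaryid"]))]
    for pt in PLANTED[:2]:
        with_pt = set(reac1.loc[reac1["pt"] == pt, "primaryid"])
        x_t, n_t = len(with_pt & tgt_pids), len(tgt_pids)
        x_c, n_c = len(with_pt & oth_pids), len(oth_pids)
        rr_hat = (x_t / n_t) / (x_c / n_c)
        se_log = math.sqrt(1 / x_t - 1 / n_t + 1 / x_c - 1 / n_c)
        assert abs(math.log(rr_hat) - math.log(8.0)) <= 3 * se_log


def test_no_duplicates_when_rate_zero(nodup_raw):
    assert nodup_raw.demo["caseid"].is_unique
    assert nodup_raw.demo["primaryid"].is_unique


def test_duplicate_versions_share_content_but_not_ids(study_raw):
    demo = study_raw.demo
    dup_cases = demo["caseid"].value_counts()
    dup_cases = set(dup_cases[dup_cases > 1].index)
    assert dup_cases, "default duplicate_rate should produce duplicates"
    grp = demo[demo["caseid"].isin(dup_cases)].sort_values(
        ["caseid", "caseversion"])
    for _, g in grp.groupby("caseid"):
        assert len(g) == 2
        v1, v2 = g.iloc[0], g.iloc[1]
        assert int(v2["primaryid"]) > int(v1["primaryid"])
        assert int(v2["fda_dt"]) > int(v1["fda_dt"])  # strictly newer
        assert v1["event_dt"] == v2["event_dt"]
        assert v1["sex"] == v2["sex"]


def test_missing_age_fraction_converges(study_raw, study_config):
    demo1 = study_raw.demo[study_raw.demo["caseversion"] == 1]
    frac = demo1["age"].isna().mean()
    p = study_config.unknown_age_frac
    se = math.sqrt(p * (1 - p) / len(demo1))
    assert abs(frac - p) <= 3 * se


def test_every_report_has_a_reaction(study_raw):
    assert set(study_raw.demo["primaryid"]) == set(study_raw.reac["primaryid"])


def test_child_tables_reference_demo(study_raw):
    pids = set(study_raw.demo["primaryid"])
    for name in ("drug", "reac", "ther", "outc"):
        assert set(getattr(study_raw, name)["primaryid"]) <= pids


def test_ground_truth_ledger_roundtrip():
    cfg = fs.SimulationConfig(seed=5)
    ledger = fs.write_ground_truth(cfg)
    assert len(ledger) == len(cfg.planted_signals)
    assert list(ledger["pt"]) == [pt for pt, _ in cfg.planted_signals]
    assert list(ledger["rr"]) == [rr for _, rr in cfg.planted_signals]

    none_planted = fs.SimulationConfig(planted_signals=(), seed=5)
    assert fs.write_ground_truth(none_planted).empty


@pytest.mark.parametrize("bad", [
    dict(p_target=1.5),
    dict(duplicate_rate=-0.1),
    dict(pt_catalog=()),
    dict(planted_signals=(("NOT_A_PT", 8.0),)),
    dict(n_reports=-1),
])
def test_invalid_config_rejected(bad):
    with pytest.raises(fs.ConfigError):
        fs.generate_dataset(fs.SimulationConfig(**bad, seed=0))
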