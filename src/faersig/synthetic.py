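"""Synthetic FAERS-like corpus generator with known ground truth.

Each logical case gets one primary-suspect (PS) drug — the target drug with
probability ``p_target``, otherwise a weighted background comparator — and a
set of reaction PTs drawn independently: PT ``j`` is included with its
baseline reporting probability ``q_j``, multiplied by the planted relative
risk ``RR_j`` (capped at 1) when the suspect drug is the target.  At least
one PT is forced per report by redrawing, since every real report carries at
least one reaction row.  A configurable fraction of cases is emitted in two
versions that differ only in FDA_DT/PRIMARYID, which makes the
keep-the-latest deduplication rule observable without disturbing
ground-truth counts.

The generative model is deliberately the simplest one consistent with the
assumptions of 2×2 disproportionality statistics: PTs independent within a
report, multiplicative risk on the target drug, demographics independent of
the reaction profile.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import ConfigError
from .tables import RawTables, TABLE_COLUMNS

_CASEID_BASE = 30_000_000
_MAX_REDRAWS = 10_000

# drug roles: PS primary suspect, SS secondary suspect, C concomitant
_CONCOMITANT_RATE = 0.3
_TARGET_AS_CONCOMITANT_RATE = 0.01


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    signals: pd.DataFrame          # columns: pt, rr
    cases: pd.DataFrame            # columns: caseid, is_target, n_versions
    planted_target_counts: pd.DataFrame  # pt, n_target_reports_with_pt
    n_logical_cases: int
    n_target_cases: int


def write_ground_truth(config: SimulationConfig) -> pd.DataFrame:
    """The planted-signal ledger: one row per (pt, relative risk)."""
    return pd.DataFrame(
        [(pt, float(rr)) for pt, rr in config.planted_signals],
        columns=["pt", "rr"],
    )


def _normalize(dist: dict) -> tuple[list, np.ndarray]:
    keys = list(dist)
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    total = probs.sum()
    if total <= 0:
        raise ConfigError("categorical distribution sums to zero")
    return keys, probs / total


def _yyyymmdd(ts: pd.Series) -> np.ndarray:
    return (ts.dt.year * 10_000 + ts.dt.month * 100 + ts.dt.day).to_numpy()


def _empty_tables() -> dict[str, pd.DataFrame]:
    return {
        name: pd.DataFrame({col: pd.Series(dtype=object) for col in cols})
        for name, cols in TABLE_COLUMNS.items()
    }


def generate_dataset(config: SimulationConfig) -> RawTables:
    """Draw one corpus; deterministic given ``config.seed``.

    The returned :class:`RawTables` carries a :class:`GroundTruth` with the
    planted signals and per-case target flags.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    if n == 0:
        empty = _empty_tables()
        truth = GroundTruth(
            signals=write_ground_truth(config),
            cases=pd.DataFrame(columns=["caseid", "is_target", "n_versions"]),
            planted_target_counts=pd.DataFrame(columns=["pt", "n_target_reports_with_pt"]),
            n_logical_cases=0, n_target_cases=0,
        )
        return RawTables(**empty, ground_truth=truth)

    caseids = np.array([str(_CASEID_BASE + i) for i in range(n)])
    is_target = rng.random(n) < config.p_target

    # --- primary-suspect drug per logical case -------------------------
    synonyms = list(config.target_drug_synonyms)
    bg_names, bg_weights = _normalize(
        {name: w for name, w in config.background_drugs})
    ps_drug = np.empty(n, dtype=object)
    n_tgt = int(is_target.sum())
    ps_drug[is_target] = rng.choice(synonyms, size=n_tgt)
    ps_drug[~is_target] = rng.choice(bg_names, size=n - n_tgt, p=bg_weights)

    # --- reaction PTs: independent Bernoulli with multiplicative risk ---
    pt_names = np.array([pt for pt, _, _ in config.pt_catalog])
    q = np.array([q_j for _, _, q_j in config.pt_catalog], dtype=float)
    probs = np.tile(q, (n, 1))
    pt_index = {pt: j for j, pt in enumerate(pt_names)}
    for pt, rr in config.planted_signals:
        j = pt_index[pt]
        probs[is_target, j] = min(1.0, q[j] * rr)
    incidence = rng.random((n, len(pt_names))) < probs
    # force >= 1 PT per report (every FAERS report has a REAC row)
    for _ in range(_MAX_REDRAWS):
        empty_rows = ~incidence.any(axis=1)
        if not empty_rows.any():
            break
        idx = np.flatnonzero(empty_rows)
        incidence[idx] = rng.random((len(idx), len(pt_names))) < probs[idx]
    else:  # pragma: no cover - requires pathological catalog
        raise ConfigError("could not draw a non-empty PT set; baseline "
                          "probabilities are too small")

    # --- demographics ---------------------------------------------------
    sex = np.where(rng.random(n) < config.unknown_sex_frac, "",
                   np.where(rng.random(n) < config.sex_probs[0], "F", "M"))
    age_known = rng.random(n) >= config.unknown_age_frac
    g_probs = np.asarray(config.age_group_probs, dtype=float)
    g_probs = g_probs / g_probs.sum()
    group = rng.choice(3, size=n, p=g_probs)
    age_years = np.where(
        group == 0, rng.uniform(0.1, 4.99, n),
        np.where(group == 1, rng.uniform(5.0, 18.99, n),
                 rng.uniform(19.0, 65.0, n)))
    # under-2s are reported in months, everyone else in whole years
    in_months = age_years < 2.0
    age = np.where(in_months, np.floor(age_years * 12), np.floor(age_years))
    age_cod = np.where(in_months, "MON", "YR").astype(object)
    age = np.where(age_known, age, np.nan)
    age_cod = np.where(age_known, age_cod, "")

    c_keys, c_probs = _normalize(config.country_probs)
    country = rng.choice(np.asarray(c_keys, dtype=object), size=n, p=c_probs)
    r_keys, r_probs = _normalize(config.reporter_probs)
    occp = rng.choice(np.asarray(r_keys, dtype=object), size=n, p=r_probs)
    o_keys, o_probs = _normalize(config.outcome_probs)
    outcome = rng.choice(np.asarray(o_keys, dtype=object), size=n, p=o_probs)

    # --- dates ----------------------------------------------------------
    y_keys, y_probs = _normalize(config.year_probs)
    years = rng.choice(np.asarray(y_keys, dtype=int), size=n, p=y_probs)
    jan1 = pd.to_datetime(pd.Series(years * 10_000 + 101), format="%Y%m%d")
    event = jan1 + pd.to_timedelta(rng.integers(0, 365, n), unit="D")
    fda_v1 = event + pd.to_timedelta(rng.integers(0, 120, n), unit="D")

    bin_lo = np.array([lo for lo, _, _ in config.onset_bins])
    bin_hi = np.array([hi for _, hi, _ in config.onset_bins])
    bin_w = np.array([w for _, _, w in config.onset_bins], dtype=float)
    bin_w = bin_w / bin_w.sum()
    onset_known = rng.random(n) < config.onset_known_frac
    which_bin = rng.choice(len(bin_w), size=n, p=bin_w)
    onset_days = rng.integers(bin_lo[which_bin], bin_hi[which_bin] + 1)
    start = event - pd.to_timedelta(onset_days, unit="D")

    event_dt = _yyyymmdd(event)
    fda_dt_v1 = _yyyymmdd(fda_v1)
    start_dt = _yyyymmdd(start)

    # --- demo: version 1 for everyone, version 2 for duplicated cases ---
    dup = rng.random(n) < config.duplicate_rate
    demo_v1 = pd.DataFrame({
        "primaryid": np.char.add(caseids.astype(str), "1"),
        "caseid": caseids,
        "caseversion": 1,
        "fda_dt": fda_dt_v1,
        "event_dt": event_dt,
        "age": age,
        "age_cod": age_cod,
        "sex": sex,
        "reporter_country": country,
        "occp_cod": occp,
    })
    dup_idx = np.flatnonzero(dup)
    fda_v2 = fda_v1.iloc[dup_idx] + pd.to_timedelta(
        rng.integers(1, 91, len(dup_idx)), unit="D")
    demo_v2 = demo_v1.iloc[dup_idx].copy()
    demo_v2["primaryid"] = np.char.add(caseids[dup_idx].astype(str), "2")
    demo_v2["caseversion"] = 2
    demo_v2["fda_dt"] = _yyyymmdd(fda_v2.reset_index(drop=True))
    demo = pd.concat([demo_v1, demo_v2], ignore_index=True)

    # --- child tables per logical case, replicated for each version -----
    def _with_versions(df: pd.DataFrame) -> pd.DataFrame:
        """Expand logical-case rows (indexed by case position) to versions."""
        v1 = df.copy()
        v1.insert(0, "primaryid", np.char.add(
            caseids[df["_case"].to_numpy()].astype(str), "1"))
        v2 = df[df["_case"].isin(dup_idx)].copy()
        v2.insert(0, "primaryid", np.char.add(
            caseids[v2["_case"].to_numpy()].astype(str), "2"))
        out = pd.concat([v1, v2], ignore_index=True)
        out.insert(1, "caseid", caseids[out["_case"].to_numpy()])
        return out.drop(columns="_case")

    drug_rows = pd.DataFrame({
        "_case": np.arange(n), "drug_seq": 1, "role_cod": "PS",
        "drugname": ps_drug, "prod_ai": ps_drug,
    })
    # add concomitant rows: background comparators, plus rare target-as-C
    # rows on non-target reports (must NOT be picked up by PS selection)
    conc = rng.random(n) < _CONCOMITANT_RATE
    conc_idx = np.flatnonzero(conc)
    conc_rows = pd.DataFrame({
        "_case": conc_idx, "drug_seq": 2, "role_cod": "C",
        "drugname": rng.choice(bg_names, size=len(conc_idx), p=bg_weights),
    })
    conc_rows["prod_ai"] = conc_rows["drugname"]
    tconc_idx = np.flatnonzero(~is_target
                               & (rng.random(n) < _TARGET_AS_CONCOMITANT_RATE))
    tconc_rows = pd.DataFrame({
        "_case": tconc_idx, "drug_seq": 3, "role_cod": "C",
        "drugname": rng.choice(synonyms, size=len(tconc_idx)),
    })
    tconc_rows["prod_ai"] = tconc_rows["drugname"]
    drug = _with_versions(
        pd.concat([drug_rows, conc_rows, tconc_rows], ignore_index=True))

    case_idx, pt_idx = np.nonzero(incidence)
    reac = _with_versions(pd.DataFrame({
        "_case": case_idx, "pt": pt_names[pt_idx],
    }))

    ther = _with_versions(pd.DataFrame({
        "_case": np.flatnonzero(onset_known),
        "dsg_drug_seq": 1,
        "start_dt": start_dt[onset_known],
    }))

    outc_mask = outcome != ""
    outc = _with_versions(pd.DataFrame({
        "_case": np.flatnonzero(outc_mask),
        "outc_cod": outcome[outc_mask],
    }))

    planted_counts = pd.DataFrame({
        "pt": [pt for pt, _ in config.planted_signals],
        "n_target_reports_with_pt": [
            int(incidence[is_target, pt_index[pt]].sum())
            for pt, _ in config.planted_signals
        ],
    })
    truth = GroundTruth(
        signals=write_ground_truth(config),
        cases=pd.DataFrame({
            "caseid": caseids, "is_target": is_target,
            "n_versions": np.where(dup, 2, 1),
        }),
        planted_target_counts=planted_counts,
        n_logical_cases=n,
        n_target_cases=n_tgt,
    )
    return RawTables(demo=demo, drug=drug, reac=reac, ther=ther, outc=outc,
                     ground_truth=truth)


def write_mapping(config: SimulationConfig, path) -> None:
    """Write the synthetic PT→SOC mapping as a two-column TSV."""
    df = pd.DataFrame(
        [(pt, soc) for pt, soc, _ in config.pt_catalog], columns=["pt", "soc"])
    df.to_csv(path, sep="\t", index=False)


def write_dataset(config: SimulationConfig, outdir, dialect: str = "ascii") -> RawTables:
    """Generate a corpus and persist it: raw tables in the requested dialect,
    the PT→SOC mapping, the planted-signal ledger and the config itself."""
    from .io import write_tables  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw = generate_dataset(config)
    write_tables(raw, outdir, dialect=dialect)
    write_mapping(config, outdir / "pt_soc_map.tsv")
    write_ground_truth(config).to_csv(
        outdir / "ground_truth.tsv", sep="\t", index=False)
    config.to_json(outdir / "sim_config.json")
    return raw
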