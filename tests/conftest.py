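from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import faersig as fs
from faersig.config import PLANTED_PTS, SOC_NAMES

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

PLANTED_SET = frozenset(pt for pt, _ in PLANTED_PTS)
N_NULL_PTS = 200


def run_screen_once(config: fs.SimulationConfig):
    """Full in-memory pipeline under one seed: generate → dedup → select →
    PT tables → statistics → four-algorithm screen."""
    raw = fs.generate_dataset(config)
    mapping = fs.TermMapping.from_catalog(config.pt_catalog)
    clean = fs.dedup_tables(raw)
    rs = fs.assemble_reports(clean, mapping, config.target_drug_synonyms)
    stats = fs.compute_all(fs.build_tables(rs, "pt"), "pt")
    return rs, fs.screen(stats)


@pytest.fixture(scope="session")
def study_config() -> fs.SimulationConfig:
    """The default study conditions (20k reports, 1% target, 5 planted PTs
    at RR=8 among 200 nulls, 20% duplication)."""
    return fs.SimulationConfig(seed=101)


@pytest.fixture(scope="session")
def study_raw(study_config):
    return fs.generate_dataset(study_config)


@pytest.fixture(scope="session")
def study_mapping(study_config):
    return fs.TermMapping.from_catalog(study_config.pt_catalog)


@pytest.fixture(scope="session")
def study_reports(study_raw, study_mapping, study_config) -> fs.ReportSet:
    clean = fs.dedup_tables(study_raw)
    return fs.assemble_reports(clean, study_mapping,
                               study_config.target_drug_synonyms)


@pytest.fixture(scope="session")
def nodup_config() -> fs.SimulationConfig:
    """Smaller corpus without duplication, for exact-count checks."""
    return fs.SimulationConfig(n_reports=4000, duplicate_rate=0.0, seed=77)


@pytest.fixture(scope="session")
def nodup_raw(nodup_config):
    return fs.generate_dataset(nodup_config)


@pytest.fixture(scope="session")
def nodup_reports(nodup_config, nodup_raw) -> fs.ReportSet:
    mapping = fs.TermMapping.from_catalog(nodup_config.pt_catalog)
    clean = fs.dedup_tables(nodup_raw)
    return fs.assemble_reports(clean, mapping,
                               nodup_config.target_drug_synonyms)


@pytest.fixture(scope="session")
def recovery_runs():
    """100 independent corpora under the default study conditions; per seed:
    the final four-algorithm signal set."""
    runs = []
    for i in range(100):
        _, screened = run_screen_once(fs.SimulationConfig(seed=20_000 + i))
        runs.append(frozenset(screened.final_signals))
    return runs


def separated_frequency_config(seed: int) -> fs.SimulationConfig:
    """Planted PTs with baseline probabilities in the frequency ratios of
    the real target-drug series (465:223:167:114:106) and a target series
    of comparable size, so the frequency ranking is identifiable."""
    qs = {"PYREXIA": 0.055, "PNEUMONIA": 0.026, "COUGH": 0.0198,
          "INFLUENZA": 0.0135, "URTICARIA": 0.0125}
    catalog = [(pt, soc, qs[pt]) for pt, soc in PLANTED_PTS]
    for i in range(N_NULL_PTS):
        catalog.append((f"PT_{i + 1:03d}", SOC_NAMES[i % len(SOC_NAMES)], 0.02))
    return fs.SimulationConfig(pt_catalog=tuple(catalog), p_target=0.05,
                               seed=seed)
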