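"""Parameterization of the synthetic spontaneous-report generator.

The generator emulates a FAERS-like corpus in which a rare enzyme-replacement
drug (laronidase, brand Aldurazyme) is the primary-suspect drug in a small
fraction of reports.  Adverse-event preferred terms (PTs) are drawn
independently per report from per-PT background reporting probabilities
``q_j``; a handful of PTs carry a planted relative-risk multiplier ``RR_j``
on reports whose suspect drug is the target, which is exactly the
multiplicative-reporting-rate situation disproportionality statistics are
built to detect.

Defaults encode the study conditions used throughout the test-bench: a
20,000-report corpus with the target drug primary-suspect in 1% of reports,
five planted signal PTs (RR = 8 on a 2% baseline) among 200 null PTs, a 20%
case-duplication rate, and demographic/outcome/onset marginals matching the
published characteristics of the laronidase report set (38.6% unknown age,
27.7% unknown sex, 73.7% US reports, 65.5% consumer reporters, 64.06% of
known onsets beyond 360 days).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

from .errors import ConfigError

#: MedDRA System Organ Class names used by the bundled synthetic PT→SOC map.
SOC_NAMES = (
    "General Disorders And Administration Site Conditions",
    "Infections And Infestations",
    "Respiratory, Thoracic And Mediastinal Disorders",
    "Skin And Subcutaneous Tissue Disorders",
    "Vascular Disorders",
    "Investigations",
    "Injury, Poisoning And Procedural Complications",
    "Nervous System Disorders",
    "Cardiac Disorders",
    "Gastrointestinal Disorders",
    "Musculoskeletal And Connective Tissue Disorders",
    "Eye Disorders",
)

#: The five planted signal PTs (the drug's most-reported real-world events).
PLANTED_PTS = (
    ("PYREXIA", SOC_NAMES[0]),
    ("PNEUMONIA", SOC_NAMES[1]),
    ("COUGH", SOC_NAMES[2]),
    ("INFLUENZA", SOC_NAMES[1]),
    ("URTICARIA", SOC_NAMES[3]),
)

DEFAULT_SYNONYMS = ("LARONIDASE", "ALDURAZYME")

#: Reporting-year distribution of the target-drug report set (2004–2024).
YEAR_COUNTS = {
    2004: 81, 2005: 60, 2006: 28, 2007: 110, 2008: 58, 2009: 56, 2010: 50,
    2011: 43, 2012: 69, 2013: 131, 2014: 127, 2015: 180, 2016: 201,
    2017: 236, 2018: 295, 2019: 263, 2020: 274, 2021: 315, 2022: 387,
    2023: 366, 2024: 347,
}


def default_pt_catalog(n_null: int = 200, baseline_prob: float = 0.02):
    """Five named signal PTs plus ``n_null`` null PTs, all at ``baseline_prob``."""
    catalog = [(pt, soc, baseline_prob) for pt, soc in PLANTED_PTS]
    for i in range(n_null):
        catalog.append((f"PT_{i + 1:03d}", SOC_NAMES[i % len(SOC_NAMES)], baseline_prob))
    return tuple(catalog)


def default_background_drugs(n: int = 40):
    """Equal-weight comparator drug names for non-target reports."""
    return tuple((f"COMPARATOR_{i + 1:03d}", 1.0) for i in range(n))


def _year_probs() -> dict[int, float]:
    total = sum(YEAR_COUNTS.values())
    return {year: count / total for year, count in YEAR_COUNTS.items()}


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic corpus.

    ``onset_bins`` are (low_day, high_day, weight) triples; within a bin the
    onset day is uniform.  ``outcome_probs`` / ``country_probs`` /
    ``reporter_probs`` are categorical distributions in which the key ``""``
    means the field is missing on the report.
    """

    n_reports: int = 20_000
    target_drug_synonyms: tuple = DEFAULT_SYNONYMS
    p_target: float = 0.01
    background_drugs: tuple = field(default_factory=default_background_drugs)
    pt_catalog: tuple = field(default_factory=default_pt_catalog)
    planted_signals: tuple = tuple((pt, 8.0) for pt, _ in PLANTED_PTS)
    duplicate_rate: float = 0.2
    unknown_age_frac: float = 0.386
    unknown_sex_frac: float = 0.277
    #: P(report carries a usable therapy-start date) — 1191 of 3677 reports.
    onset_known_frac: float = 0.324
    onset_bins: tuple = (
        (0, 30, 0.1200),
        (31, 60, 0.0400),
        (61, 90, 0.0300),
        (91, 180, 0.0600),
        (181, 360, 0.1094),
        (361, 1825, 0.6406),
    )
    outcome_probs: dict = field(default_factory=lambda: {
        "HO": 0.275, "DE": 0.166, "CA": 0.001, "LT": 0.015,
        "DS": 0.019, "OT": 0.213, "": 0.311,
    })
    country_probs: dict = field(default_factory=lambda: {
        "US": 0.737, "BR": 0.032, "GB": 0.077, "FR": 0.066,
        "JP": 0.051, "DE": 0.037,
    })
    reporter_probs: dict = field(default_factory=lambda: {
        "CN": 0.655, "MD": 0.220, "HP": 0.061, "PH": 0.014,
        "RN": 0.001, "": 0.049,
    })
    year_probs: dict = field(default_factory=_year_probs)
    #: among reports with known age: P(<5), P(5–18), P(>18)
    age_group_probs: tuple = (0.259, 0.466, 0.275)
    sex_probs: tuple = (0.498, 0.502)  # F vs M among known-sex reports
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ConfigError("n_reports must be non-negative")
        if not self.target_drug_synonyms:
            raise ConfigError("target_drug_synonyms must be non-empty")
        if not self.pt_catalog:
            raise ConfigError("pt_catalog must be non-empty")
        for name, prob in [
            ("p_target", self.p_target),
            ("duplicate_rate", self.duplicate_rate),
            ("unknown_age_frac", self.unknown_age_frac),
            ("unknown_sex_frac", self.unknown_sex_frac),
            ("onset_known_frac", self.onset_known_frac),
        ]:
            if not 0.0 <= prob <= 1.0:
                raise ConfigError(f"{name}={prob!r} is not a probability in [0, 1]")
        names = [pt for pt, _, _ in self.pt_catalog]
        if len(names) != len(set(names)):
            raise ConfigError("pt_catalog names must be unique")
        for pt, _, q in self.pt_catalog:
            if not 0.0 <= q <= 1.0:
                raise ConfigError(f"baseline probability for {pt} not in [0, 1]")
        known = set(names)
        for pt, rr in self.planted_signals:
            if pt not in known:
                raise ConfigError(f"planted signal PT {pt!r} not in pt_catalog")
            if rr < 0:
                raise ConfigError(f"relative risk for {pt} must be >= 0")
        for label, dist in [
            ("outcome_probs", self.outcome_probs),
            ("country_probs", self.country_probs),
            ("reporter_probs", self.reporter_probs),
            ("year_probs", self.year_probs),
        ]:
            if not dist:
                raise ConfigError(f"{label} must be non-empty")
            if any(p < 0 for p in dist.values()):
                raise ConfigError(f"{label} has a negative probability")
        if any(w < 0 for _, _, w in self.onset_bins) or not self.onset_bins:
            raise ConfigError("onset_bins weights must be non-negative")
        if any(hi < lo for lo, hi, _ in self.onset_bins):
            raise ConfigError("onset_bins must have high >= low")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)
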