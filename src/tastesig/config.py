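"""Configuration: dialects, case definition, thresholds.

A :class:`DialectConfig` describes how one spontaneous-reporting-system (SRS)
dump maps onto the common case-level data model: column names per table, role
codes accepted as "suspect" exposure, how ages and sexes are coded, and how
adverse-event terms map to MedDRA preferred-term (PT) codes.  Two dialects are
shipped: a FAERS-style one (dollar-delimited ASCII, case versioning, a THER
table with therapy start dates) and a JADER-style one (CSV with Japanese
headers, decade-bucketed ages, no versioning).

The case definition — the set of PT codes that together constitute the target
adverse event — is plain configuration; the default is the four taste-disorder
terms (taste disorder, dysgeusia, hypogeusia, ageusia).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

# MedDRA preferred-term codes defining the target adverse event (taste
# disorders).  Codes are opaque integers; no hierarchy traversal is done.
TASTE_DISORDER_PT_CODES: dict[str, int] = {
    "Taste disorder": 10082490,
    "Dysgeusia": 10013911,
    "Hypogeusia": 10020989,
    "Ageusia": 10001480,
}

# FAERS age-unit codes -> factor converting to years.
FAERS_AGE_UNITS: dict[str, float] = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

# JADER decade buckets -> midpoint age in years.
JADER_AGE_BUCKETS: dict[str, float] = {f"{d}歳代": d + 5.0 for d in range(0, 110, 10)}
JADER_AGE_BUCKETS.update({"10歳未満": 5.0, "100歳以上": 100.0})

JADER_SEX_MAP: dict[str, str] = {"男性": "male", "女性": "female", "不明": ""}


@dataclass
class DialectConfig:
    """Column layout and code maps for one SRS dialect."""

    name: str
    delimiter: str
    columns: dict[str, dict[str, str]]  # table -> logical field -> column name
    suspect_roles: tuple[str, ...]  # role codes accepted as exposure
    sex_map: dict[str, str]  # raw sex code -> male/female ("" = missing)
    age_units: dict[str, float] = field(default_factory=dict)
    age_buckets: dict[str, float] = field(default_factory=dict)
    unknown_markers: tuple[str, ...] = ("", "UNK", "NS", "不明")
    pt_name_to_code: dict[str, int] = field(
        default_factory=lambda: dict(TASTE_DISORDER_PT_CODES)
    )


def faers_dialect() -> DialectConfig:
    """Default FAERS quarterly-ASCII dialect (post-2014 column era)."""
    return DialectConfig(
        name="FAERS",
        delimiter="$",
        columns={
            "demo": {
                "primaryid": "primaryid",
                "case_id": "caseid",
                "version": "caseversion",
                "age": "age",
                "age_unit": "age_cod",
                "sex": "sex",
                "occupation": "occp_cod",
            },
            "drug": {
                "primaryid": "primaryid",
                "case_id": "caseid",
                "drug_seq": "drug_seq",
                "role": "role_cod",
                "drug_name": "drugname",
            },
            "reac": {
                "primaryid": "primaryid",
                "case_id": "caseid",
                "pt_name": "pt",
                "onset_date": "event_dt",
            },
            "ther": {
                "primaryid": "primaryid",
                "case_id": "caseid",
                "drug_seq": "dsg_drug_seq",
                "start_date": "start_dt",
            },
        },
        suspect_roles=("PS",),
        sex_map={"M": "male", "F": "female", "UNK": "", "NS": ""},
        age_units=dict(FAERS_AGE_UNITS),
    )


def jader_dialect() -> DialectConfig:
    """Default JADER CSV dialect (Japanese headers, decade ages)."""
    return DialectConfig(
        name="JADER",
        delimiter=",",
        columns={
            "demo": {
                "case_id": "識別番号",
                "version": "報告回数",
                "age": "年齢",
                "sex": "性別",
                "occupation": "報告者職種",
            },
            "drug": {
                "case_id": "識別番号",
                "role": "医薬品の関与",
                "drug_name": "医薬品（一般名）",
                "start_date": "投与開始日",
            },
            "reac": {
                "case_id": "識別番号",
                "pt_name": "有害事象",
                "onset_date": "有害事象の発現日",
            },
            "hist": {
                "case_id": "識別番号",
                "history": "原疾患等",
            },
        },
        suspect_roles=("被疑薬",),
        sex_map=dict(JADER_SEX_MAP),
        age_buckets=dict(JADER_AGE_BUCKETS),
    )


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Thresholds follow standard SRS practice for this analysis: a drug enters
    signal screening at >=5 target-event cases, time-to-onset analysis at
    >=20 onset records, and the adjusted-odds-ratio model at >=30 cases
    (10 events per variable x 3 explanatory variables).
    """

    target_pt_codes: tuple[int, ...] = tuple(TASTE_DISORDER_PT_CODES.values())
    drug_list: tuple[str, ...] = ()
    atc_codes: Mapping[str, str] = field(default_factory=dict)
    min_cases_signal: int = 5
    min_cases_tto: int = 20
    min_cases_adjusted: int = 30
    max_plausible_age: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_pt_codes:
            raise ValueError("target_pt_codes must be non-empty")
        for name in ("min_cases_signal", "min_cases_tto", "min_cases_adjusted"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from a YAML key-value file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "target_pt_codes" in raw:
        raw["target_pt_codes"] = tuple(int(c) for c in raw["target_pt_codes"])
    if "drug_list" in raw:
        raw["drug_list"] = tuple(raw["drug_list"])
    return PipelineConfig(**raw)
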