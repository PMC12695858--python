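"""Synthetic spontaneous-reporting-system data with known ground truth.

The generator emulates the structure the cleaning and analysis stages
assume: multi-version case submissions, a primary-suspect drug per report,
partially missing or precision-degraded dates (year-only, year-month,
full), age/sex demographics, a logistic case-status model (base reporting
rate x per-drug odds multiplier x optional age/sex effects) and
drug-specific Weibull-distributed onset intervals. It emits the same FAERS
and JADER dialects the ingestion module reads, alongside a ground-truth
table recording, per report, the true exposure, case status, onset
interval and every planted defect — so every downstream stage can be
tested against a known answer without any database download.

Reproducibility: one scenario seed is expanded into fixed per-component
substreams (demographics, exposure, outcome, onset, dates, defects), so
the same seed yields byte-identical output files.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TARGET_AE_TERMS = ("Taste disorder", "Dysgeusia", "Hypogeusia", "Ageusia")
OTHER_AE_TERMS = (
    "Nausea", "Headache", "Rash", "Fatigue", "Diarrhoea",
    "Dizziness", "Pyrexia", "Vomiting",
)
FAERS_OCCUPATIONS = ("MD", "PH", "CN", "OT", "HP")
JADER_OCCUPATIONS = ("医師", "薬剤師", "消費者等", "その他医療専門家")

_START_LO = datetime.date(2015, 1, 1).toordinal()
_START_HI = datetime.date(2023, 12, 31).toordinal()

# fixed spawn order of the per-component random substreams
_STREAMS = ("demo", "exposure", "outcome", "onset", "dates", "defects", "misc")


@dataclass
class SimulationScenario:
    """All knobs of one synthetic SRS study, with realistic defaults.

    ``drug_effects`` are odds multipliers for the target adverse event;
    ``onset_models`` map drug name to (weibull_shape, weibull_scale_days).
    ``age_effect`` is log-odds per year of age (centred at 50 years) and
    ``sex_effect`` log-odds for female sex, so the adjusted-odds-ratio
    stage has a recoverable confounding structure. ``missingness`` gives
    per-field defect probabilities (keys: age, sex, start_date,
    event_date, anomalous_age); ``date_year_month`` / ``date_year_only``
    degrade date precision per date field.
    """

    n_reports: int = 1000
    drug_catalog: tuple[tuple[str, float], ...] = (
        ("drugA", 0.10), ("drugB", 0.15), ("drugC", 0.25), ("drugD", 0.50),
    )
    target_ae_base_rate: float = 0.02
    drug_effects: Mapping[str, float] = field(default_factory=dict)
    age_mean: float = 55.0
    age_sd: float = 18.0
    sex_ratio_female: float = 0.55
    age_effect: float = 0.0
    sex_effect: float = 0.0
    onset_models: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    missingness: Mapping[str, float] = field(default_factory=dict)
    date_year_month: float = 0.0
    date_year_only: float = 0.0
    duplicate_rate: float = 0.0
    floor_onset_half_day: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        names = {n for n, _ in self.drug_catalog}
        if not names:
            raise ValueError("drug_catalog must be non-empty")
        for d in self.drug_effects:
            if d not in names:
                raise ValueError(f"drug effect for unknown drug {d!r}")
        for d, (shape, scale) in self.onset_models.items():
            if d not in names:
                raise ValueError(f"onset model for unknown drug {d!r}")
            if shape <= 0 or scale <= 0:
                raise ValueError("Weibull shape and scale must be positive")
        probs = [p for _, p in self.drug_catalog]
        probs += [self.target_ae_base_rate, self.sex_ratio_female,
                  self.duplicate_rate, self.date_year_month, self.date_year_only]
        probs += list(self.missingness.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(c)
                for name, c in zip(_STREAMS, children)}


def simulate_onset_sample(
    shape: float, scale: float, n: int,
    seed: int | None = None, rng: np.random.Generator | None = None,
    floor_half_day: bool = False,
) -> np.ndarray:
    """I.i.d. Weibull onset times by inverse-CDF from a seeded uniform stream.

    ``t = scale * (-ln(1 - u))**(1/shape)``; optionally floored at the
    0.5-day same-day convention to mirror ingestion.
    """
    if shape <= 0 or scale <= 0:
        raise ValueError("Weibull shape and scale must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random(n)
    t = scale * (-np.log1p(-u)) ** (1.0 / shape)
    if floor_half_day:
        t = np.maximum(t, 0.5)
    return t


def _expected_interval(start_prec, onset_prec, start_ord, onset_ord):
    """What ingestion should recover from the planted dates, or NaN.

    Mirrors the partial-date rules: year-only on either side excludes the
    record; year-month dates are imputed to day 15; negative intervals are
    excluded; zero becomes 0.5.
    """
    def imputed(prec, ordinal):
        if prec == "year":
            return None
        if prec == "year_month":
            d = datetime.date.fromordinal(int(ordinal))
            return datetime.date(d.year, d.month, 15).toordinal()
        return int(ordinal)

    s, o = imputed(start_prec, start_ord), imputed(onset_prec, onset_ord)
    if s is None or o is None:
        return math.nan
    delta = o - s
    if delta < 0:
        return math.nan
    return 0.5 if delta == 0 else float(delta)


def simulate_cohort(scenario: SimulationScenario) -> pd.DataFrame:
    """Ground-truth frame: one row per unique case, defects annotated."""
    n = scenario.n_reports
    rngs = scenario.rngs()
    names = np.array([d for d, _ in scenario.drug_catalog])
    probs = np.array([p for _, p in scenario.drug_catalog], dtype=float)
    probs = probs / probs.sum()

    age = np.clip(rngs["demo"].normal(scenario.age_mean, scenario.age_sd, n), 0, 100)
    female = rngs["demo"].random(n) < scenario.sex_ratio_female
    occ = rngs["demo"].integers(0, len(FAERS_OCCUPATIONS), n)

    drug = names[rngs["exposure"].choice(len(names), size=n, p=probs)]
    base = scenario.target_ae_base_rate
    logit = (
        math.log(base / (1 - base))
        + np.log([scenario.drug_effects.get(d, 1.0) for d in drug])
        + scenario.age_effect * (age - 50.0)
        + scenario.sex_effect * female
    )
    is_case = rngs["outcome"].random(n) < 1.0 / (1.0 + np.exp(-logit))

    onset = np.empty(n)
    for d in names:
        mask = drug == d
        shape, scale = scenario.onset_models.get(d, (1.0, 30.0))
        onset[mask] = simulate_onset_sample(
            shape, scale, int(mask.sum()), rng=rngs["onset"],
            floor_half_day=scenario.floor_onset_half_day,
        )

    start_ord = rngs["dates"].integers(_START_LO, _START_HI + 1, n)
    onset_ord = start_ord + np.floor(onset).astype(int)

    # planted defects
    miss = scenario.missingness
    rd = rngs["defects"]
    def plant(key):
        return rd.random(n) < float(miss.get(key, 0.0))

    miss_age = plant("age")
    anom_age = plant("anomalous_age") & ~miss_age
    miss_sex = plant("sex") & ~(miss_age | anom_age)
    miss_start = plant("start_date")
    miss_event = plant("event_date")

    def precision(rng):
        r = rng.random(n)
        prec = np.full(n, "full", dtype=object)
        prec[r < scenario.date_year_month + scenario.date_year_only] = "year_month"
        prec[r < scenario.date_year_only] = "year"
        return prec

    start_prec = precision(rngs["dates"])
    onset_prec = precision(rngs["dates"])
    dup = rd.random(n) < scenario.duplicate_rate

    if (scenario.date_year_month == 0.0 and scenario.date_year_only == 0.0
            and not (miss_start.any() or miss_event.any())):
        # full-precision dates: the recovered interval is just the day delta
        delta = (onset_ord - start_ord).astype(float)
        expected = np.where(delta == 0.0, 0.5, delta).tolist()
    else:
        expected = [
            math.nan
            if (miss_start[i] or miss_event[i])
            else _expected_interval(start_prec[i], onset_prec[i],
                                    start_ord[i], onset_ord[i])
            for i in range(n)
        ]

    ae_term = np.where(
        is_case,
        np.array(TARGET_AE_TERMS)[rngs["misc"].integers(0, len(TARGET_AE_TERMS), n)],
        np.array(OTHER_AE_TERMS)[rngs["misc"].integers(0, len(OTHER_AE_TERMS), n)],
    )

    return pd.DataFrame(
        {
            "case_id": [f"C{100000 + i}" for i in range(n)],
            "drug": drug,
            "age": np.round(age, 1),
            "female": female,
            "occupation_idx": occ,
            "is_case": is_case,
            "ae_term": ae_term,
            "onset_days_true": onset,
            "start_ordinal": start_ord,
            "onset_ordinal": onset_ord,
            "start_precision": start_prec,
            "onset_precision": onset_prec,
            "missing_age": miss_age,
            "anomalous_age": anom_age,
            "missing_sex": miss_sex,
            "missing_start_date": miss_start,
            "missing_event_date": miss_event,
            "duplicate_version": dup,
            "interval_days_expected": expected,
        }
    )


def _fmt_date_faers(ordinal: int, precision: str) -> str:
    d = datetime.date.fromordinal(int(ordinal))
    if precision == "year":
        return f"{d.year:04d}"
    if precision == "year_month":
        return f"{d.year:04d}{d.month:02d}"
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def _fmt_date_jader(ordinal: int, precision: str) -> str:
    d = datetime.date.fromordinal(int(ordinal))
    if precision == "year":
        return f"{d.year:04d}"
    if precision == "year_month":
        return f"{d.year:04d}/{d.month:02d}"
    return f"{d.year:04d}/{d.month:02d}/{d.day:02d}"


@dataclass
class SimulatedData:
    truth: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    dialect: str


def _faers_tables(truth: pd.DataFrame) -> dict[str, pd.DataFrame]:
    demo_rows, drug_rows, reac_rows, ther_rows = [], [], [], []
    for t in truth.itertuples(index=False):
        versions = [1, 2] if t.duplicate_version else [1]
        final = versions[-1]
        for v in versions:
            pid = f"{t.case_id}-{v}"
            is_final = v == final
            if not is_final:
                # earlier versions are emitted incomplete on purpose, so a
                # dedup failure is visible downstream
                age, age_cod = "", ""
            elif t.missing_age:
                age, age_cod = "", ""
            elif t.anomalous_age:
                age, age_cod = "-5", "YR"
            else:
                age, age_cod = f"{t.age:.1f}", "YR"
            sex = "" if (t.missing_sex and is_final) else ("F" if t.female else "M")
            demo_rows.append(
                (pid, t.case_id, str(v), age, age_cod, sex,
                 FAERS_OCCUPATIONS[t.occupation_idx])
            )
            drug_rows.append((pid, t.case_id, "1", "PS", t.drug))
            reac_rows.append(
                (pid, t.case_id, t.ae_term,
                 "" if t.missing_event_date
                 else _fmt_date_faers(t.onset_ordinal, t.onset_precision))
            )
            ther_rows.append(
                (pid, t.case_id, "1",
                 "" if t.missing_start_date
                 else _fmt_date_faers(t.start_ordinal, t.start_precision))
            )
    return {
        "demo": pd.DataFrame(demo_rows, columns=[
            "primaryid", "caseid", "caseversion", "age", "age_cod", "sex",
            "occp_cod"]),
        "drug": pd.DataFrame(drug_rows, columns=[
            "primaryid", "caseid", "drug_seq", "role_cod", "drugname"]),
        "reac": pd.DataFrame(reac_rows, columns=[
            "primaryid", "caseid", "pt", "event_dt"]),
        "ther": pd.DataFrame(ther_rows, columns=[
            "primaryid", "caseid", "dsg_drug_seq", "start_dt"]),
    }


def _jader_tables(truth: pd.DataFrame) -> dict[str, pd.DataFrame]:
    demo_rows, drug_rows, reac_rows, hist_rows = [], [], [], []
    for t in truth.itertuples(index=False):
        copies = 2 if t.duplicate_version else 1  # exact duplicates
        if t.missing_age:
            age = ""
        elif t.anomalous_age:
            age = "成人"  # non-numeric bucket text: anomalous, not blank
        else:
            age = f"{int(t.age // 10) * 10}歳代"
        sex = "不明" if t.missing_sex else ("女性" if t.female else "男性")
        occ = JADER_OCCUPATIONS[t.occupation_idx % len(JADER_OCCUPATIONS)]
        for _ in range(copies):
            demo_rows.append((t.case_id, "1", sex, age, occ))
            drug_rows.append(
                (t.case_id, "被疑薬", t.drug,
                 "" if t.missing_start_date
                 else _fmt_date_jader(t.start_ordinal, t.start_precision))
            )
            reac_rows.append(
                (t.case_id, t.ae_term,
                 "" if t.missing_event_date
                 else _fmt_date_jader(t.onset_ordinal, t.onset_precision))
            )
            hist_rows.append((t.case_id, "高血圧"))
    return {
        "demo": pd.DataFrame(demo_rows, columns=[
            "識別番号", "報告回数", "性別", "年齢", "報告者職種"]),
        "drug": pd.DataFrame(drug_rows, columns=[
            "識別番号", "医薬品の関与", "医薬品（一般名）", "投与開始日"]),
        "reac": pd.DataFrame(reac_rows, columns=[
            "識別番号", "有害事象", "有害事象の発現日"]),
        "hist": pd.DataFrame(hist_rows, columns=["識別番号", "原疾患等"]),
    }


def simulate_reports(
    scenario: SimulationScenario,
    dialect: str = "faers",
    outdir: str | Path | None = None,
) -> SimulatedData:
    """Generate raw dialect tables (optionally written to disk) + truth.

    FAERS output is dollar-delimited ``demo.txt``/``drug.txt``/``reac.txt``/
    ``ther.txt``; JADER output is CSV ``demo.csv`` etc.; the ground truth is
    written as ``truth.csv``. Same seed, same bytes.
    """
    truth = simulate_cohort(scenario)
    if dialect == "faers":
        tables = _faers_tables(truth)
        sep, suffix = "$", "txt"
    elif dialect == "jader":
        tables = _jader_tables(truth)
        sep, suffix = ",", "csv"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.{suffix}", sep=sep, index=False,
                      lineterminator="\n")
        truth.to_csv(outdir / "truth.csv", index=False, lineterminator="\n")
    return SimulatedData(truth=truth, tables=tables, dialect=dialect)
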