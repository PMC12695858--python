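"""Reading, cleaning and normalizing spontaneous-reporting-system tables.

The two supported dialects (FAERS-style dollar-delimited ASCII and
JADER-style CSV) are normalized into one case-level data model:

* ``reports`` — one row per (case_id, version): demographics and, after
  labelling, the case indicator;
* ``drugs``   — one row per reported drug: normalized name, canonical role,
  therapy start date as a partial date;
* ``events``  — one row per reported adverse event: MedDRA PT code/name and
  onset date as a partial date.

Cleaning follows conventional SRS practice: keep only the latest version of
each case; exclude reports with blank or anomalous age, sex, therapy start
date or event date (tallied per reason for the attrition flowchart); label
cases by PT-code membership; and derive time-to-onset with the usual
partial-date conventions (year-only dates excluded, year-month dates imputed
to day 15, onset before start excluded, same-day onset set to 0.5 days).
"""

from __future__ import annotations

import csv
import datetime
import hashlib
import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .config import DialectConfig, faers_dialect, jader_dialect

log = logging.getLogger("tastesig")

# Canonical drug-role vocabulary; dialect role codes map onto these.
ROLE_MAP = {
    "PS": "primary_suspect",
    "SS": "suspect",
    "C": "concomitant",
    "I": "interacting",
    "被疑薬": "suspect",
    "併用薬": "concomitant",
    "相互作用": "interacting",
}
# Roles counted as exposure, per dialect: FAERS restricts to the primary
# suspect drug; JADER has no PS/SS split, so suspected drugs qualify.
ACCEPTED_ROLES = {"FAERS": ("primary_suspect",), "JADER": ("suspect",)}

EXCLUSION_REASONS = (
    "missing_age",
    "anomalous_age",
    "missing_sex",
    "missing_start_date",
    "missing_event_date",
)


# ---------------------------------------------------------------------------
# text and date normalization


def normalize_text(s: str) -> str:
    """NFKC-fold (full-width -> half-width), trim, collapse whitespace."""
    s = unicodedata.normalize("NFKC", str(s))
    return re.sub(r"\s+", " ", s).strip()


def normalize_drug_name(s: str) -> str:
    """Canonical drug-name key: NFKC + casefold + whitespace collapse.

    Salt forms ("sunitinib malate") stay distinct keys on purpose.
    """
    return normalize_text(s).casefold()


@dataclass(frozen=True)
class PartialDate:
    """A calendar date known to year, year-month or full precision."""

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            if self.month is None:
                raise ValueError("day given without month")
            datetime.date(self.year, self.month, self.day)  # validates

    @property
    def precision(self) -> str:
        if self.month is None:
            return "year"
        if self.day is None:
            return "year_month"
        return "full"

    def imputed_ordinal(self) -> int | None:
        """Proleptic-Gregorian day number with the day-15 convention.

        Year-month dates get day := 15; year-only dates are not imputable
        and return ``None`` (the caller excludes the record).
        """
        if self.month is None:
            return None
        return datetime.date(self.year, self.month, self.day or 15).toordinal()


_DATE_SPLIT = re.compile(r"[/\-.]")


def parse_partial_date(raw) -> PartialDate | None:
    """Parse a dialect date string into a :class:`PartialDate`.

    Accepts compact numeric forms (``YYYY``, ``YYYYMM``, ``YYYYMMDD``) and
    separated forms (``YYYY/MM/DD`` etc.); a trailing time portion is
    dropped. Unparseable or blank input returns ``None`` — the record is
    then handled by the relevant exclusion rule rather than raising.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = normalize_text(raw).split(" ")[0]
    if not s:
        return None
    try:
        if s.isdigit():
            if len(s) == 4:
                return PartialDate(int(s))
            if len(s) == 6:
                return PartialDate(int(s[:4]), int(s[4:6]))
            if len(s) == 8:
                return PartialDate(int(s[:4]), int(s[4:6]), int(s[6:8]))
            return None
        parts = [p for p in _DATE_SPLIT.split(s) if p]
        if not 1 <= len(parts) <= 3 or not all(p.isdigit() for p in parts):
            return None
        nums = [int(p) for p in parts]
        if nums[0] < 1000:
            return None
        return PartialDate(*nums)
    except ValueError:
        return None


def pt_code_for(name: str, dialect: DialectConfig) -> int:
    """PT code for a term name: configured map, else a stable positive hash.

    Codes are opaque integers here; unmapped terms only need a consistent
    non-target identity, which a digest of the normalized name provides.
    """
    key = normalize_text(name)
    code = dialect.pt_name_to_code.get(key)
    if code is not None:
        return int(code)
    digest = hashlib.sha1(key.casefold().encode()).hexdigest()
    return 10_000_000 + int(digest[:8], 16) % 80_000_000


# ---------------------------------------------------------------------------
# case-level data model


@dataclass
class CaseData:
    """Normalized case-level tables for one source database."""

    source: str
    reports: pd.DataFrame  # case_id, version, age_years, sex, occupation[, is_case]
    drugs: pd.DataFrame  # case_id, drug_name, role, start_year/month/day
    events: pd.DataFrame  # case_id, pt_code, pt_name, onset_year/month/day
    accepted_roles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.accepted_roles:
            self.accepted_roles = ACCEPTED_ROLES.get(self.source, ("suspect",))

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def exposed_ids(self, drug_name: str) -> set:
        """Case ids exposed to ``drug_name`` through an accepted role."""
        key = normalize_drug_name(drug_name)
        d = self.drugs
        mask = (d["drug_name"] == key) & d["role"].isin(self.accepted_roles)
        return set(d.loc[mask, "case_id"])


@dataclass(frozen=True)
class DrugEntry:
    drug_name: str
    role: str
    start_date: PartialDate | None


@dataclass(frozen=True)
class EventEntry:
    pt_code: int
    pt_name: str
    onset_date: PartialDate | None


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated, cleaned safety report (object view for iteration)."""

    case_id: str
    source: str
    age_years: float
    sex: str
    reporter_occupation: str
    drugs: tuple[DrugEntry, ...]
    events: tuple[EventEntry, ...]
    is_case: bool = False


def _pd_from_row(row, prefix: str) -> PartialDate | None:
    y = row[f"{prefix}_year"]
    if pd.isna(y):
        return None
    m = row[f"{prefix}_month"]
    d = row[f"{prefix}_day"]
    try:
        return PartialDate(
            int(y), None if pd.isna(m) else int(m), None if pd.isna(d) else int(d)
        )
    except ValueError:
        return None


def iter_case_reports(data: CaseData) -> Iterator[CaseReport]:
    """Materialize :class:`CaseReport` objects (test/oracle convenience)."""
    drugs_by_case: dict = {k: v for k, v in data.drugs.groupby("case_id")}
    events_by_case: dict = {k: v for k, v in data.events.groupby("case_id")}
    for _, r in data.reports.iterrows():
        cid = r["case_id"]
        dd = drugs_by_case.get(cid)
        ee = events_by_case.get(cid)
        yield CaseReport(
            case_id=cid,
            source=data.source,
            age_years=float(r["age_years"]),
            sex=r["sex"],
            reporter_occupation=r.get("occupation", ""),
            drugs=tuple(
                DrugEntry(d["drug_name"], d["role"], _pd_from_row(d, "start"))
                for _, d in (dd.iterrows() if dd is not None else ())
            ),
            events=tuple(
                EventEntry(int(e["pt_code"]), e["pt_name"], _pd_from_row(e, "onset"))
                for _, e in (ee.iterrows() if ee is not None else ())
            ),
            is_case=bool(r["is_case"]) if "is_case" in r else False,
        )


# ---------------------------------------------------------------------------
# raw table readers


def _read_delimited(path: str | Path, delimiter: str) -> tuple[pd.DataFrame, int]:
    """Read a header+rows delimited text table, rejecting malformed lines.

    Returns the frame (all columns as strings) and the count of rejected
    lines (wrong field count), which are logged, not raised.
    """
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, no header row")
        rows, bad = [], 0
        for lineno, fields in enumerate(reader, start=2):
            if not fields:
                continue
            if len(fields) != len(header):
                bad += 1
                log.warning("%s:%d: expected %d fields, got %d — line rejected",
                            path, lineno, len(header), len(fields))
                continue
            rows.append(fields)
    if bad:
        log.warning("%s: rejected %d malformed line(s)", path, bad)
    return pd.DataFrame(rows, columns=[h.strip() for h in header], dtype=str), bad


def _require(df: pd.DataFrame, mapping: dict[str, str], table: str, path) -> None:
    for logical, col in mapping.items():
        if col not in df.columns:
            raise ValueError(f"{path}: {table} table is missing required column "
                             f"'{col}' (field '{logical}')")


def _clean_missing(s: pd.Series, dialect: DialectConfig) -> pd.Series:
    s = s.fillna("").map(normalize_text)
    return s.where(~s.isin(dialect.unknown_markers), "")


def _age_to_years(age_raw: pd.Series, unit_raw: pd.Series | None,
                  dialect: DialectConfig) -> tuple[pd.Series, pd.Series]:
    """Convert dialect age coding to years.

    Returns (age_years, flag) where flag is ``ok``/``missing``/``anomalous``.
    Unconvertible units or bucket text count as anomalous (the value is
    present but unusable); blank input counts as missing.
    """
    n = len(age_raw)
    years = pd.Series(np.nan, index=age_raw.index, dtype=float)
    flag = pd.Series("missing", index=age_raw.index, dtype=object)
    for i in age_raw.index:
        a = age_raw.at[i]
        if a == "":
            continue
        if dialect.age_buckets:
            if a in dialect.age_buckets:
                years.at[i] = dialect.age_buckets[a]
                flag.at[i] = "ok"
                continue
            m = re.fullmatch(r"(\d+)歳", a)
            if m:
                years.at[i] = float(m.group(1))
                flag.at[i] = "ok"
            else:
                flag.at[i] = "anomalous"
            continue
        try:
            val = float(a)
        except ValueError:
            flag.at[i] = "anomalous"
            continue
        unit = unit_raw.at[i] if unit_raw is not None else "YR"
        factor = dialect.age_units.get(unit or "YR")
        if factor is None:
            flag.at[i] = "anomalous"
            log.warning("unconvertible age unit %r treated as anomalous", unit)
            continue
        years.at[i] = val * factor
        flag.at[i] = "ok"
    assert len(years) == n
    return years, flag


def _date_cols(s: pd.Series, prefix: str) -> pd.DataFrame:
    parsed = s.map(parse_partial_date)
    return pd.DataFrame(
        {
            f"{prefix}_year": [p.year if p else np.nan for p in parsed],
            f"{prefix}_month": [
                p.month if p and p.month is not None else np.nan for p in parsed
            ],
            f"{prefix}_day": [
                p.day if p and p.day is not None else np.nan for p in parsed
            ],
        },
        index=s.index,
    )


@dataclass
class RawTables:
    """Dialect-normalized tables prior to dedup/exclusion."""

    source: str
    demo: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    rejected_lines: int = 0


def read_faers_tables(
    demo_path, drug_path, reac_path, ther_path,
    dialect: DialectConfig | None = None,
) -> RawTables:
    """Read FAERS-style DEMO/DRUG/REAC/THER dollar-delimited tables.

    DEMO supplies demographics and the case version; DRUG supplies names and
    role codes; REAC supplies event terms and onset dates; THER supplies
    therapy start dates, joined onto DRUG by (primaryid, drug sequence).
    """
    dialect = dialect or faers_dialect()
    cols = dialect.columns
    rejected = 0

    demo, bad = _read_delimited(demo_path, dialect.delimiter)
    rejected += bad
    _require(demo, cols["demo"], "DEMO", demo_path)
    c = cols["demo"]
    age_raw = _clean_missing(demo[c["age"]], dialect)
    unit_raw = _clean_missing(demo[c["age_unit"]], dialect)
    age_years, age_flag = _age_to_years(age_raw, unit_raw, dialect)
    ndemo = pd.DataFrame(
        {
            "primaryid": demo[c["primaryid"]].map(normalize_text),
            "case_id": demo[c["case_id"]].map(normalize_text),
            "version": pd.to_numeric(demo[c["version"]], errors="coerce")
            .fillna(0).astype(int),
            "age_years": age_years,
            "age_flag": age_flag,
            "sex": _clean_missing(demo[c["sex"]], dialect).map(
                lambda s: dialect.sex_map.get(s, "")
            ),
            "occupation": _clean_missing(demo[c["occupation"]], dialect),
        }
    )

    drug, bad = _read_delimited(drug_path, dialect.delimiter)
    rejected += bad
    _require(drug, cols["drug"], "DRUG", drug_path)
    c = cols["drug"]
    ndrug = pd.DataFrame(
        {
            "primaryid": drug[c["primaryid"]].map(normalize_text),
            "case_id": drug[c["case_id"]].map(normalize_text),
            "drug_seq": drug[c["drug_seq"]].map(normalize_text),
            "drug_name": drug[c["drug_name"]].map(normalize_drug_name),
            "role": _clean_missing(drug[c["role"]], dialect).map(
                lambda r: ROLE_MAP.get(r, "other")
            ),
        }
    )

    ther, bad = _read_delimited(ther_path, dialect.delimiter)
    rejected += bad
    _require(ther, cols["ther"], "THER", ther_path)
    c = cols["ther"]
    nther = pd.DataFrame(
        {
            "primaryid": ther[c["primaryid"]].map(normalize_text),
            "drug_seq": ther[c["drug_seq"]].map(normalize_text),
        }
    )
    nther = pd.concat([nther, _date_cols(ther[c["start_date"]], "start")], axis=1)
    # a drug may have several therapy episodes; the earliest start is used
    nther = nther.sort_values(
        ["primaryid", "drug_seq", "start_year", "start_month", "start_day"]
    ).drop_duplicates(["primaryid", "drug_seq"], keep="first")
    ndrug = ndrug.merge(nther, on=["primaryid", "drug_seq"], how="left")

    reac, bad = _read_delimited(reac_path, dialect.delimiter)
    rejected += bad
    _require(reac, cols["reac"], "REAC", reac_path)
    c = cols["reac"]
    nreac = pd.DataFrame(
        {
            "primaryid": reac[c["primaryid"]].map(normalize_text),
            "case_id": reac[c["case_id"]].map(normalize_text),
            "pt_name": reac[c["pt_name"]].map(normalize_text),
        }
    )
    nreac["pt_code"] = nreac["pt_name"].map(lambda n: pt_code_for(n, dialect))
    nreac = pd.concat([nreac, _date_cols(reac[c["onset_date"]], "onset")], axis=1)

    return RawTables("FAERS", ndemo, ndrug, nreac, rejected)


def read_jader_tables(
    demo_path, drug_path, reac_path, hist_path=None,
    dialect: DialectConfig | None = None,
) -> RawTables:
    """Read JADER-style CSV tables with Japanese headers.

    Full-width/half-width variants collapse to one normalized form,
    "unknown" markers become missing, and exact duplicate rows (after
    normalization) are removed; JADER carries no FAERS-style versioning, so
    every report gets version 1. HIST is accepted for interface parity but
    only passed through.
    """
    dialect = dialect or jader_dialect()
    cols = dialect.columns
    rejected = 0

    demo, bad = _read_delimited(demo_path, dialect.delimiter)
    rejected += bad
    _require(demo, {k: v for k, v in cols["demo"].items() if k != "version"},
             "DEMO", demo_path)
    c = cols["demo"]
    age_raw = _clean_missing(demo[c["age"]], dialect)
    age_years, age_flag = _age_to_years(age_raw, None, dialect)
    ndemo = pd.DataFrame(
        {
            "case_id": demo[c["case_id"]].map(normalize_text),
            "version": 1,
            "age_years": age_years,
            "age_flag": age_flag,
            "sex": _clean_missing(demo[c["sex"]], dialect).map(
                lambda s: dialect.sex_map.get(s, "")
            ),
            "occupation": _clean_missing(demo[c["occupation"]], dialect),
        }
    )
    ndemo["primaryid"] = ndemo["case_id"]
    ndemo = ndemo.drop_duplicates(subset=["case_id"], keep="last")

    drug, bad = _read_delimited(drug_path, dialect.delimiter)
    rejected += bad
    _require(drug, cols["drug"], "DRUG", drug_path)
    c = cols["drug"]
    ndrug = pd.DataFrame(
        {
            "case_id": drug[c["case_id"]].map(normalize_text),
            "drug_name": drug[c["drug_name"]].map(normalize_drug_name),
            "role": _clean_missing(drug[c["role"]], dialect).map(
                lambda r: ROLE_MAP.get(r, "other")
            ),
        }
    )
    ndrug["primaryid"] = ndrug["case_id"]
    ndrug = pd.concat([ndrug, _date_cols(drug[c["start_date"]], "start")], axis=1)
    ndrug = ndrug.drop_duplicates()

    reac, bad = _read_delimited(reac_path, dialect.delimiter)
    rejected += bad
    _require(reac, cols["reac"], "REAC", reac_path)
    c = cols["reac"]
    nreac = pd.DataFrame(
        {
            "case_id": reac[c["case_id"]].map(normalize_text),
            "pt_name": reac[c["pt_name"]].map(normalize_text),
        }
    )
    nreac["primaryid"] = nreac["case_id"]
    nreac["pt_code"] = nreac["pt_name"].map(lambda n: pt_code_for(n, dialect))
    nreac = pd.concat([nreac, _date_cols(reac[c["onset_date"]], "onset")], axis=1)
    nreac = nreac.drop_duplicates()

    return RawTables("JADER", ndemo, ndrug, nreac, rejected)


# ---------------------------------------------------------------------------
# dedup, exclusions, labelling


def dedup_latest_version(rows: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per case_id: the maximal version, last-read on ties.

    Idempotent; an empty frame passes through unchanged.
    """
    if rows.empty:
        return rows.copy()
    # stable sort keeps input order within (case_id, version); keep="last"
    # then resolves exact ties by ingestion order
    out = (
        rows.sort_values("version", kind="stable")
        .drop_duplicates(subset=["case_id"], keep="last")
        .sort_index()
    )
    return out.reset_index(drop=True)


def dedup_tables(raw: RawTables) -> RawTables:
    """Apply latest-version dedup to DEMO and align the detail tables."""
    demo = dedup_latest_version(raw.demo)
    keep = set(demo["primaryid"])
    return RawTables(
        raw.source,
        demo,
        raw.drugs[raw.drugs["primaryid"].isin(keep)].reset_index(drop=True),
        raw.events[raw.events["primaryid"].isin(keep)].reset_index(drop=True),
        raw.rejected_lines,
    )


def apply_exclusions(
    raw: RawTables, max_plausible_age: float = 120.0
) -> tuple[CaseData, dict[str, int]]:
    """Drop reports with blank/anomalous age, sex, start date or event date.

    Each report is tallied under the first matching reason (fixed order:
    missing_age, anomalous_age, missing_sex, missing_start_date,
    missing_event_date), so survivors + sum(tally) equals the input count
    exactly — the attrition-flowchart identity.
    """
    demo = raw.demo
    has_start = set(
        raw.drugs.loc[raw.drugs["start_year"].notna(), "primaryid"]
    )
    has_event_date = set(
        raw.events.loc[raw.events["onset_year"].notna(), "primaryid"]
    )

    age_bad_range = demo["age_years"].notna() & (
        (demo["age_years"] < 0) | (demo["age_years"] > max_plausible_age)
    )
    reason = pd.Series("", index=demo.index, dtype=object)
    checks = [
        ("missing_age", demo["age_flag"] == "missing"),
        ("anomalous_age", (demo["age_flag"] == "anomalous") | age_bad_range),
        ("missing_sex", ~demo["sex"].isin(["male", "female"])),
        ("missing_start_date", ~demo["primaryid"].isin(has_start)),
        ("missing_event_date", ~demo["primaryid"].isin(has_event_date)),
    ]
    for name, mask in checks:
        reason = reason.where((reason != "") | ~mask, name)

    tally = {name: int((reason == name).sum()) for name in EXCLUSION_REASONS}
    surv = demo[reason == ""].reset_index(drop=True)
    keep = set(surv["primaryid"])
    reports = surv[["case_id", "version", "age_years", "sex", "occupation"]].copy()
    reports["is_case"] = False

    data = CaseData(
        source=raw.source,
        reports=reports,
        drugs=raw.drugs[raw.drugs["primaryid"].isin(keep)]
        .drop(columns=["primaryid"])
        .reset_index(drop=True),
        events=raw.events[raw.events["primaryid"].isin(keep)]
        .drop(columns=["primaryid"])
        .reset_index(drop=True),
    )
    for name, n in tally.items():
        if n:
            log.info("excluded %d report(s): %s", n, name)
    return data, tally


def label_cases(data: CaseData, target_pt_codes: Iterable[int]) -> CaseData:
    """Set ``is_case`` on every report: any event PT in the target set.

    Never drops reports; raises on an empty target set.
    """
    targets = {int(c) for c in target_pt_codes}
    if not targets:
        raise ValueError("target PT code set must be non-empty")
    case_ids = set(
        data.events.loc[data.events["pt_code"].isin(targets), "case_id"]
    )
    reports = data.reports.copy()
    reports["is_case"] = reports["case_id"].isin(case_ids)
    return replace(data, reports=reports)


# ---------------------------------------------------------------------------
# time-to-onset derivation


ONSET_RULES = (
    "rule1_year_only_excluded",
    "rule2_day_imputed_15",
    "rule3_onset_before_start_excluded",
    "rule4_same_day_half_day",
)


def compute_onset(
    data: CaseData, drug_name: str, target_pt_codes: Iterable[int]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Time-to-onset records for one drug among labelled case reports.

    For every case report exposed to the drug (accepted role), the interval
    runs from the therapy start date to the earliest target-event onset
    date, in exact calendar days, with:

    * year-only precision on either date -> record excluded (rule 1);
    * year-month precision -> day imputed to 15 (rule 2, tallied);
    * onset before start -> excluded (rule 3);
    * onset on the start day -> 0.5 days (rule 4).

    Returns (records, tally): records has columns case_id / drug_name /
    time_to_onset_days; the tally counts each rule's firings plus
    ``emitted``.
    """
    targets = {int(c) for c in target_pt_codes}
    key = normalize_drug_name(drug_name)
    tally = {r: 0 for r in ONSET_RULES}
    tally["emitted"] = 0

    if "is_case" not in data.reports.columns:
        raise ValueError("reports must be labelled before onset derivation")
    case_ids = set(data.reports.loc[data.reports["is_case"], "case_id"])

    d = data.drugs
    exposed = d[
        (d["drug_name"] == key)
        & d["role"].isin(data.accepted_roles)
        & d["case_id"].isin(case_ids)
    ]
    ev = data.events[data.events["pt_code"].isin(targets)]
    events_by_case = {k: v for k, v in ev.groupby("case_id")}

    out = []
    for cid, rows in exposed.groupby("case_id", sort=False):
        # a report naming the drug twice still yields one onset record:
        # earliest start date wins
        starts = [
            (pd_.imputed_ordinal(), pd_.precision)
            for _, r in rows.iterrows()
            if (pd_ := _pd_from_row(r, "start")) is not None
        ]
        start_full = [o for o, _ in starts if o is not None]
        if not start_full:
            tally["rule1_year_only_excluded"] += 1
            continue
        start_ord = min(start_full)
        start_imputed = any(
            prec == "year_month" for o, prec in starts if o == start_ord
        )

        evs = events_by_case.get(cid)
        onset_ord, onset_imputed = None, False
        if evs is not None:
            for _, e in evs.iterrows():
                p = _pd_from_row(e, "onset")
                if p is None:
                    continue
                o = p.imputed_ordinal()
                if o is None:
                    continue
                if onset_ord is None or o < onset_ord:
                    onset_ord, onset_imputed = o, p.precision == "year_month"
        if onset_ord is None:
            # all target-event dates were year-only or absent
            tally["rule1_year_only_excluded"] += 1
            continue

        if start_imputed or onset_imputed:
            tally["rule2_day_imputed_15"] += 1
        delta = onset_ord - start_ord
        if delta < 0:
            tally["rule3_onset_before_start_excluded"] += 1
            continue
        if delta == 0:
            tally["rule4_same_day_half_day"] += 1
            days = 0.5
        else:
            days = float(delta)
        out.append((cid, key, days))
        tally["emitted"] += 1

    records = pd.DataFrame(out, columns=["case_id", "drug_name", "time_to_onset_days"])
    return records, tally


# ---------------------------------------------------------------------------
# interchange files


def write_interchange(data: CaseData, outdir: str | Path) -> None:
    """Persist the normalized case-level model as plain CSV + JSON meta."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.reports.to_csv(outdir / "reports.csv", index=False)
    data.drugs.to_csv(outdir / "drugs.csv", index=False)
    data.events.to_csv(outdir / "events.csv", index=False)
    meta = {"source": data.source, "accepted_roles": list(data.accepted_roles)}
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))


def read_interchange(indir: str | Path) -> CaseData:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    reports = pd.read_csv(indir / "reports.csv", dtype={"case_id": str})
    drugs = pd.read_csv(indir / "drugs.csv", dtype={"case_id": str})
    events = pd.read_csv(indir / "events.csv", dtype={"case_id": str})
    return CaseData(
        source=meta["source"],
        reports=reports,
        drugs=drugs,
        events=events,
        accepted_roles=tuple(meta["accepted_roles"]),
    )
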