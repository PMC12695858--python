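"""End-to-end pipeline, attrition bookkeeping and paper-style tables.

``run_pipeline`` chains the stages — dedup, exclusions, case labelling,
signal screening, time-to-onset fits and adjusted odds ratios — over one
raw dialect dump and emits one output directory of delimited tables plus a
machine-readable run log. ``verify_printed_tables`` recomputes the signal
statistics from a packaged file of published 2x2 margins and checks them
cell by cell at display precision; it is the built-in correctness harness
for the disproportionality formulas.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .adjusted import adjusted_summary_table
from .config import PipelineConfig, TASTE_DISORDER_PT_CODES
from .ingest import (
    CaseData,
    RawTables,
    apply_exclusions,
    compute_onset,
    dedup_tables,
    label_cases,
    normalize_drug_name,
)
from .signals import ContingencyTable, evaluate_table, round_half_up, \
    screen_signals, signal_table
from .tto import onset_summary_table

log = logging.getLogger("tastesig")

AGE_BIN_EDGES = (20, 30, 40, 50, 60, 70, 80, 90)
AGE_BIN_LABELS = ("<19", "20-29", "30-39", "40-49", "50-59", "60-69",
                  "70-79", "80-89", ">90")


def clean(
    raw: RawTables, config: PipelineConfig
) -> tuple[CaseData, dict[str, int]]:
    """Dedup + exclusions + case labelling, with attrition counts.

    The returned tally satisfies, exactly:
    raw reports = duplicates removed + per-reason exclusions + survivors.
    """
    n_raw = len(raw.demo)
    deduped = dedup_tables(raw)
    data, tally = apply_exclusions(deduped, config.max_plausible_age)
    data = label_cases(data, config.target_pt_codes)
    attrition = {
        "raw_reports": n_raw,
        "duplicate_versions_removed": n_raw - len(deduped.demo),
        **tally,
        "survivors": data.n_reports,
        "cases": int(data.reports["is_case"].sum()),
    }
    return data, attrition


def demographics_table(data: CaseData) -> pd.DataFrame:
    """Characteristics of case reports: AE term, sex, age decade, reporter.

    Age decades use half-open bins (<19 means below 20, >90 means 90 and
    above); each block's counts sum to the case count.
    """
    cases = data.reports[data.reports["is_case"]]
    ids = set(cases["case_id"])
    n = len(cases)
    rows: list[dict] = []

    def add(block: str, label: str, count: int) -> None:
        rows.append({
            "block": block, "category": label, "count": int(count),
            "percent": round(100.0 * count / n, 1) if n else 0.0,
        })

    target_names = {v: k for k, v in TASTE_DISORDER_PT_CODES.items()}
    ev = data.events[data.events["case_id"].isin(ids)]
    ev = ev[ev["pt_code"].isin(target_names)]
    # one AE contribution per (case, term)
    term_counts = (
        ev.drop_duplicates(["case_id", "pt_code"])["pt_code"]
        .map(target_names).value_counts()
    )
    for term, cnt in term_counts.items():
        add("adverse_event", term, cnt)

    for sex in ("male", "female"):
        add("sex", sex, (cases["sex"] == sex).sum())

    bins = np.digitize(cases["age_years"].to_numpy(float), AGE_BIN_EDGES)
    for k, label in enumerate(AGE_BIN_LABELS):
        add("age_decade", label, (bins == k).sum())

    occ = cases["occupation"].fillna("").replace("", "missing")
    for label, cnt in occ.value_counts().items():
        add("reporter_occupation", label, cnt)
    return pd.DataFrame(rows)


def run_pipeline(
    raw: RawTables,
    config: PipelineConfig,
    outdir: str | Path,
) -> dict[str, pd.DataFrame]:
    """Run every stage and write the full artifact bundle.

    Outputs (all plain delimited text in ``outdir``): ``attrition.csv``,
    ``demographics.csv``, ``signals.csv``, ``time_to_onset.csv``,
    ``adjusted_ror.csv`` and ``run_log.json``. All frames are computed
    before anything is written, so a stage failure leaves no partial
    bundle behind.
    """
    data, attrition = clean(raw, config)

    drug_list = [normalize_drug_name(d) for d in config.drug_list]
    if not drug_list:
        drug_list = sorted(
            set(
                data.drugs.loc[
                    data.drugs["role"].isin(data.accepted_roles), "drug_name"
                ]
            )
        )
    results = screen_signals(data, drug_list, min_cases=config.min_cases_signal)
    sig = signal_table(results)
    atc = {normalize_drug_name(k): v for k, v in dict(config.atc_codes).items()}
    if atc:
        sig["atc_code"] = sig["drug"].map(lambda d: atc.get(d, ""))

    onset_by_drug: dict[str, pd.DataFrame] = {}
    onset_tallies: dict[str, dict[str, int]] = {}
    for drug in drug_list:
        rec, tally = compute_onset(data, drug, config.target_pt_codes)
        onset_by_drug[drug] = rec
        onset_tallies[drug] = tally
    tto = onset_summary_table(onset_by_drug, min_cases=config.min_cases_tto)

    adj = adjusted_summary_table(data, drug_list,
                                 min_cases=config.min_cases_adjusted)
    demo = demographics_table(data)
    attr = pd.DataFrame(
        [{"step": k, "count": v} for k, v in attrition.items()]
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = {
        "attrition": attr,
        "demographics": demo,
        "signals": sig,
        "time_to_onset": tto,
        "adjusted_ror": adj,
    }
    for name, df in frames.items():
        df.to_csv(outdir / f"{name}.csv", index=False, lineterminator="\n")
    run_log = {
        "package_version": __version__,
        "source": raw.source,
        "seed": config.seed,
        "thresholds": {
            "min_cases_signal": config.min_cases_signal,
            "min_cases_tto": config.min_cases_tto,
            "min_cases_adjusted": config.min_cases_adjusted,
        },
        "target_pt_codes": list(config.target_pt_codes),
        "onset_rule_tallies": onset_tallies,
        "attrition": attrition,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=1,
                                                    sort_keys=True))
    return frames


# ---------------------------------------------------------------------------
# verification against published 2x2 margins


def load_published_margins(margins_file: str | Path | None = None) -> pd.DataFrame:
    """Published per-drug 2x2 margins + printed statistics (packaged CSV)."""
    if margins_file is None:
        ref = resources.files("tastesig").joinpath("data/table3_margins.csv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p)
    path = Path(margins_file)
    if not path.exists():
        raise FileNotFoundError(f"margins fixture not found: {path}")
    return pd.read_csv(path)


def verify_printed_tables(margins_file: str | Path | None = None) -> pd.DataFrame:
    """Recompute ROR/CI/IC/IC025 from published margins; compare at 2 d.p.

    Returns one row per (drug, statistic) with the recomputed value, the
    printed value and a pass flag; every statistic of every row passing is
    the expected state.
    """
    margins = load_published_margins(margins_file)
    checks = []
    for row in margins.itertuples(index=False):
        table = ContingencyTable.from_margins(
            int(row.n11), int(row.n10), int(row.nplus1), int(row.nplusplus)
        )
        res = evaluate_table(table, drug_name=row.drug)
        computed = {
            "ror": res.ror_result.ror,
            "ci_low": res.ror_result.ci_low,
            "ci_high": res.ror_result.ci_high,
            "ic": res.ic_result.ic,
            "ic025": res.ic_result.ic025,
        }
        for stat, value in computed.items():
            printed = float(getattr(row, stat))
            got = round_half_up(value, 2)
            checks.append({
                "drug": row.drug, "statistic": stat,
                "computed": got, "printed": printed,
                "passed": abs(got - printed) < 1e-9,
            })
    return pd.DataFrame(checks)
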