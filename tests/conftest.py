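import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import tastesig as ts

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


FAERS_DEMO = """\
primaryid$caseid$caseversion$age$age_cod$sex$occp_cod
100-1$100$1$60$YR$F$MD
100-2$100$2$61$YR$F$MD
200-1$200$1$24$MON$M$CN
"""

FAERS_DRUG = """\
primaryid$caseid$drug_seq$role_cod$drugname
100-1$100$1$PS$Drugex
100-2$100$1$PS$Drugex
200-1$200$1$PS$Otherol
200-1$200$2$C$Drugex
"""

FAERS_REAC = """\
primaryid$caseid$pt$event_dt
100-1$100$Dysgeusia$20230110
100-2$100$Dysgeusia$20230110
200-1$200$Nausea$20230405
"""

FAERS_THER = """\
primaryid$caseid$dsg_drug_seq$start_dt
100-1$100$1$20230101
100-2$100$1$20230101
200-1$200$1$20230401
"""


@pytest.fixture
def faers_dir(tmp_path):
    """Tiny hand-written FAERS-dialect dump: 2 cases, one with 2 versions."""
    (tmp_path / "demo.txt").write_text(FAERS_DEMO)
    (tmp_path / "drug.txt").write_text(FAERS_DRUG)
    (tmp_path / "reac.txt").write_text(FAERS_REAC)
    (tmp_path / "ther.txt").write_text(FAERS_THER)
    return tmp_path


def make_case_data(rows):
    """Build a CaseData directly from compact per-report tuples.

    Each row: (case_id, age, sex, is_case, drugs, events) with drugs a list
    of (name, role, (y, m, d)) and events a list of (pt_code, (y, m, d));
    date parts may be None for partial precision, or the date itself None.
    """
    reports, drugs, events = [], [], []
    for case_id, age, sex, is_case, drow, erow in rows:
        reports.append(
            {"case_id": case_id, "version": 1, "age_years": age, "sex": sex,
             "occupation": "MD", "is_case": is_case}
        )
        for name, role, date in drow:
            y, m, d = date if date else (np.nan, np.nan, np.nan)
            drugs.append(
                {"case_id": case_id, "drug_name": ts.normalize_drug_name(name),
                 "role": role, "start_year": y,
                 "start_month": m if m is not None else np.nan,
                 "start_day": d if d is not None else np.nan}
            )
        for pt_code, date in erow:
            y, m, d = date if date else (np.nan, np.nan, np.nan)
            events.append(
                {"case_id": case_id, "pt_code": pt_code, "pt_name": "term",
                 "onset_year": y,
                 "onset_month": m if m is not None else np.nan,
                 "onset_day": d if d is not None else np.nan}
            )
    return ts.CaseData(
        source="FAERS",
        reports=pd.DataFrame(reports),
        drugs=pd.DataFrame(drugs),
        events=pd.DataFrame(events),
    )


@pytest.fixture(scope="session")
def cleaned_synth():
    """A moderately sized cleaned synthetic dataset shared across tests."""
    sc = ts.SimulationScenario(
        n_reports=5000, seed=42,
        drug_effects={"drugA": 8.0, "drugB": 1.0},
        onset_models={"drugA": (0.6, 20.0)},
        missingness={"age": 0.02, "sex": 0.02, "start_date": 0.03,
                     "event_date": 0.03, "anomalous_age": 0.01},
        date_year_month=0.05, date_year_only=0.02, duplicate_rate=0.04,
    )
    sim = ts.simulate_reports(sc, dialect="faers")
    raw = _raw_from_tables(sim.tables)
    data, attrition = ts.clean(raw, ts.PipelineConfig(seed=42))
    return sim, raw, data, attrition


def _raw_from_tables(tables):
    """Route in-memory dialect tables through the real file readers."""
    import tempfile
    from pathlib import Path

    d = Path(tempfile.mkdtemp())
    for name, df in tables.items():
        df.to_csv(d / f"{name}.txt", sep="$", index=False, lineterminator="\n")
    return ts.read_faers_tables(
        d / "demo.txt", d / "drug.txt", d / "reac.txt", d / "ther.txt"
    )
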