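"""Age- and sex-adjusted reporting odds ratios via logistic regression.

For one drug, each cleaned report contributes an observation to

    log-odds(case) = b0 + bD * D + bA * A + bG * G

where D indicates exposure to the drug (accepted role), A is age in years
(continuous) and G indicates female sex. The adjusted reporting odds ratio
is ``exp(bD)`` with a Wald 95% CI. Following the events-per-variable rule
of thumb (EPV = 10, three explanatory variables), the model is fitted only
for drugs with at least 30 target-event cases. Multicollinearity is
monitored with variance inflation factors (VIFs) over the three
explanatory columns; VIF >= 2 is reported as a warning, not a failure.

Fits are maximum likelihood via statsmodels; the drug-only submodel is
algebraically identical to the closed-form 2x2 reporting odds ratio, which
downstream tests exploit as an oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ingest import CaseData

log = logging.getLogger("tastesig")

EPV = 10  # events per explanatory variable
N_EXPLANATORY = 3  # drug, age, sex
VIF_WARN = 2.0


class SeparationError(RuntimeError):
    """A D x outcome cell is empty: the drug coefficient is not estimable."""


@dataclass(frozen=True)
class AdjustedRorResult:
    drug_name: str
    n11: int
    crude_ror: float
    crude_ci: tuple[float, float]
    adjusted_ror: float
    adjusted_ci: tuple[float, float]
    coefficients: Mapping[str, float]  # const, drug, age, female (log-odds)
    vif: Mapping[str, float]
    eligible: bool


def build_design(data: CaseData, drug_name: str) -> pd.DataFrame:
    """One observation per cleaned, labelled report.

    Columns: ``outcome`` (case indicator), ``drug`` (exposure through an
    accepted role), ``age`` (years), ``female``. Refuses degenerate designs
    with no exposed or no case observations.
    """
    if "is_case" not in data.reports.columns:
        raise ValueError("reports must be labelled before building a design")
    exposed = data.exposed_ids(drug_name)
    r = data.reports
    design = pd.DataFrame(
        {
            "outcome": r["is_case"].astype(int).to_numpy(),
            "drug": r["case_id"].isin(exposed).astype(int).to_numpy(),
            "age": r["age_years"].astype(float).to_numpy(),
            "female": (r["sex"] == "female").astype(int).to_numpy(),
        }
    )
    if design["drug"].sum() == 0:
        raise ValueError(f"no reports exposed to {drug_name!r}: fit refused")
    if design["outcome"].sum() == 0:
        raise ValueError("no case observations: fit refused")
    return design


def _vif(cols: pd.DataFrame) -> dict[str, float]:
    """VIF per column from auxiliary least-squares regressions."""
    out: dict[str, float] = {}
    x = cols.to_numpy(dtype=float)
    for j, name in enumerate(cols.columns):
        yj = x[:, j]
        others = np.column_stack([np.ones(len(x)), np.delete(x, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        sst = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
        out[name] = 1.0 / (1.0 - r2) if r2 < 1.0 else math.inf
    return out


def _logit_fit(design: pd.DataFrame, covariates: Sequence[str]):
    y = design["outcome"].to_numpy()
    x = sm.add_constant(design[list(covariates)], has_constant="add")
    model = sm.Logit(y, x)
    res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-8)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("logistic fit did not converge")
    return res


def fit_adjusted(design: pd.DataFrame, drug_name: str = "",
                 min_cases: int = EPV * N_EXPLANATORY) -> AdjustedRorResult:
    """Crude and age/sex-adjusted reporting odds ratio for one design."""
    ct = pd.crosstab(design["drug"], design["outcome"])
    if ct.shape != (2, 2) or (ct.to_numpy() == 0).any():
        raise SeparationError(
            f"empty exposure x outcome cell for {drug_name!r}; "
            "odds ratio not estimable"
        )
    n11 = int(((design["drug"] == 1) & (design["outcome"] == 1)).sum())
    eligible = n11 >= min_cases

    crude = _logit_fit(design, ["drug"])
    adj = _logit_fit(design, ["drug", "age", "female"])

    def _or_ci(res) -> tuple[float, tuple[float, float]]:
        b = float(res.params["drug"])
        se = float(res.bse["drug"])
        return math.exp(b), (math.exp(b - 1.96 * se), math.exp(b + 1.96 * se))

    crude_or, crude_ci = _or_ci(crude)
    adj_or, adj_ci = _or_ci(adj)
    vif = _vif(design[["drug", "age", "female"]])
    bad = {k: v for k, v in vif.items() if v >= VIF_WARN}
    if bad:
        log.warning("VIF >= %.1f for %s: %s", VIF_WARN, drug_name or "drug", bad)

    params = adj.params
    return AdjustedRorResult(
        drug_name=drug_name,
        n11=n11,
        crude_ror=crude_or,
        crude_ci=crude_ci,
        adjusted_ror=adj_or,
        adjusted_ci=adj_ci,
        coefficients={
            "const": float(params["const"]),
            "drug": float(params["drug"]),
            "age": float(params["age"]),
            "female": float(params["female"]),
        },
        vif=vif,
        eligible=eligible,
    )


def adjusted_summary_table(
    data: CaseData, drug_list: Sequence[str], min_cases: int = EPV * N_EXPLANATORY
) -> pd.DataFrame:
    """Crude/adjusted odds-ratio rows for drugs meeting the case gate."""
    rows = []
    for name in drug_list:
        try:
            design = build_design(data, name)
        except ValueError:
            continue
        n11 = int(((design["drug"] == 1) & (design["outcome"] == 1)).sum())
        if n11 < min_cases:
            continue
        res = fit_adjusted(design, drug_name=name, min_cases=min_cases)
        rows.append(
            {
                "drug": name,
                "cases": res.n11,
                "total": int(design["drug"].sum()),
                "crude_ror": round(res.crude_ror, 2),
                "crude_ci_low": round(res.crude_ci[0], 2),
                "crude_ci_high": round(res.crude_ci[1], 2),
                "adjusted_ror": round(res.adjusted_ror, 2),
                "adjusted_ci_low": round(res.adjusted_ci[0], 2),
                "adjusted_ci_high": round(res.adjusted_ci[1], 2),
            }
        )
    cols = ["drug", "cases", "total", "crude_ror", "crude_ci_low",
            "crude_ci_high", "adjusted_ror", "adjusted_ci_low",
            "adjusted_ci_high"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("cases", ascending=False).reset_index(drop=True)
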