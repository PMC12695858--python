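"""Disproportionality signal detection: ROR and BCPNN information component.

Signal detection works on a 2x2 contingency table of report counts for one
drug against one target adverse-event (AE) set::

                      target AE   other AEs   total
    target drug          N11         N10       N1+
    all other drugs      N01         N00       N0+
    total                N+1         N+0       N++

Two disproportionality statistics are computed per drug:

* the reporting odds ratio ``ROR = (N11/N10) / (N01/N00)`` with a log-scale
  Wald 95% confidence interval, signalling when the lower bound exceeds 1;
* the Bayesian Confidence Propagation Neural Network (BCPNN) information
  component ``IC = log2`` of the posterior observed-to-expected reporting
  ratio under Dirichlet priors (gamma11 = 1, alpha1 = beta1 = 1,
  alpha = beta = 2), with a +/- 2 standard-deviation credible interval,
  signalling when IC025 > 0.

A drug-AE pair is called a signal when both criteria fire and the drug has
at least ``min_cases`` (default 5) target-AE reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .ingest import CaseData, normalize_drug_name

# BCPNN Dirichlet prior constants (joint cell and the two margins).
GAMMA11 = 1.0
ALPHA1 = BETA1 = 1.0
ALPHA = BETA = 2.0

LN2_SQ = math.log(2.0) ** 2


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report counts for one drug x one AE set."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n1plus(self) -> int:
        return self.n11 + self.n10

    @property
    def n0plus(self) -> int:
        return self.n01 + self.n00

    @property
    def nplus1(self) -> int:
        return self.n11 + self.n01

    @property
    def nplus0(self) -> int:
        return self.n10 + self.n00

    @property
    def nplusplus(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @classmethod
    def from_margins(cls, n11: int, n10: int, nplus1: int, nplusplus: int
                     ) -> "ContingencyTable":
        """Reconstruct the table from the cells a summary table prints."""
        n01 = nplus1 - n11
        n00 = nplusplus - (n11 + n10) - n01
        return cls(n11, n10, n01, n00)


@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    signal: bool
    defined: bool = True


@dataclass(frozen=True)
class IcResult:
    ic: float
    variance: float
    ic025: float
    ic975: float
    signal: bool
    prior_gamma: float


@dataclass(frozen=True)
class SignalResult:
    drug_name: str
    n11: int
    ror_result: RorResult
    ic_result: IcResult
    eligible: bool
    atc_code: str = ""
    n10: int = 0  # exposed non-case reports
    low_expected: bool = False  # expected joint count N1+*N+1/N++ below 5

    @property
    def signal(self) -> bool:
        return self.eligible and self.ror_result.signal and self.ic_result.signal


def ror(table: ContingencyTable) -> RorResult:
    """Reporting odds ratio with log-scale Wald 95% CI.

    Any zero cell makes the cross-ratio undefined; such tables are returned
    flagged (``defined=False``) with NaN estimates and no signal rather
    than raising — the >=5-case eligibility gate removes them from
    screening anyway.
    """
    if min(table.n11, table.n10, table.n01, table.n00) == 0:
        return RorResult(math.nan, math.nan, math.nan, signal=False, defined=False)
    est = (table.n11 / table.n10) / (table.n01 / table.n00)
    half = 1.96 * math.sqrt(
        1 / table.n11 + 1 / table.n10 + 1 / table.n01 + 1 / table.n00
    )
    lo, hi = math.exp(math.log(est) - half), math.exp(math.log(est) + half)
    return RorResult(est, lo, hi, signal=lo > 1.0)


def information_component(table: ContingencyTable) -> IcResult:
    """BCPNN expected information component and 95% credible interval.

    With N = N++ and the prior constants above, the joint-cell prior weight
    gamma is chosen so the prior IC expectation is null::

        gamma = gamma11 * (N+alpha)(N+beta) / ((N1+ + alpha1)(N+1 + beta1))

        E(IC) = log2 [ (N11+gamma11)(N+alpha)(N+beta)
                       / ((N+gamma)(N1+ + alpha1)(N+1 + beta1)) ]

    The variance is the standard three-term closed form over the joint cell
    and the two margins, scaled by 1/ln(2)^2; the credible bounds are
    E(IC) +/- 2*sqrt(V).
    """
    n = table.nplusplus
    if n <= 0:
        raise ValueError("total report count must be positive")
    n11, n1p, np1 = table.n11, table.n1plus, table.nplus1
    gamma = GAMMA11 * (n + ALPHA) * (n + BETA) / ((n1p + ALPHA1) * (np1 + BETA1))
    e_ic = math.log2(
        (n11 + GAMMA11) * (n + ALPHA) * (n + BETA)
        / ((n + gamma) * (n1p + ALPHA1) * (np1 + BETA1))
    )
    v = (
        (n - n11 + gamma - GAMMA11) / ((n11 + GAMMA11) * (1 + n + gamma))
        + (n - n1p + ALPHA - ALPHA1) / ((n1p + ALPHA1) * (1 + n + ALPHA))
        + (n - np1 + BETA - BETA1) / ((np1 + BETA1) * (1 + n + BETA))
    ) / LN2_SQ
    sd2 = 2.0 * math.sqrt(v)
    return IcResult(
        ic=e_ic,
        variance=v,
        ic025=e_ic - sd2,
        ic975=e_ic + sd2,
        signal=e_ic - sd2 > 0.0,
        prior_gamma=gamma,
    )


def build_contingency(data: CaseData, drug_name: str) -> ContingencyTable:
    """2x2 table for one drug over labelled case reports.

    One report is one observation: exposure is membership of the drug
    (accepted role) in the report's drug list, outcome is the report's case
    label, so the four cells always sum to the number of reports.
    """
    if "is_case" not in data.reports.columns:
        raise ValueError("reports must be labelled before building tables")
    exposed = data.exposed_ids(drug_name)
    r = data.reports
    is_exp = r["case_id"].isin(exposed)
    is_case = r["is_case"].astype(bool)
    n11 = int((is_exp & is_case).sum())
    n10 = int((is_exp & ~is_case).sum())
    n01 = int((~is_exp & is_case).sum())
    n00 = int((~is_exp & ~is_case).sum())
    return ContingencyTable(n11, n10, n01, n00)


def evaluate_table(
    table: ContingencyTable, drug_name: str = "", atc_code: str = "",
    min_cases: int = 5,
) -> SignalResult:
    """Run both disproportionality statistics on a ready-made table."""
    expected = (
        table.n1plus * table.nplus1 / table.nplusplus if table.nplusplus else 0.0
    )
    return SignalResult(
        drug_name=drug_name,
        n11=table.n11,
        ror_result=ror(table),
        ic_result=information_component(table),
        eligible=table.n11 >= min_cases,
        atc_code=atc_code,
        n10=table.n10,
        low_expected=expected < 5,
    )


def screen_signals(
    data: CaseData, drug_list: Sequence[str], min_cases: int = 5
) -> list[SignalResult]:
    """Screen a drug list; a signal needs both criteria plus eligibility."""
    if not drug_list:
        raise ValueError("drug_list must be non-empty")
    # results are keyed by the normalized name so that lists from different
    # databases intersect cleanly
    results = [
        evaluate_table(build_contingency(data, name),
                       drug_name=normalize_drug_name(name),
                       min_cases=min_cases)
        for name in drug_list
    ]
    results.sort(key=lambda r: r.n11, reverse=True)
    return results


def cross_database_intersection(
    faers_results: Iterable[SignalResult], jader_results: Iterable[SignalResult]
) -> list[str]:
    """Drugs signal-positive in both databases, FAERS case count descending."""
    jader_pos = {r.drug_name for r in jader_results if r.signal}
    faers_pos = sorted(
        (r for r in faers_results if r.signal), key=lambda r: r.n11, reverse=True
    )
    return [r.drug_name for r in faers_pos if r.drug_name in jader_pos]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, the convention used for displayed statistics."""
    if x != x:  # NaN
        return x
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def signal_table(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Summary frame with the usual signal-table columns (2 d.p. display)."""
    rows = []
    for r in results:
        rr, ic = r.ror_result, r.ic_result
        rows.append(
            {
                "drug": r.drug_name,
                "atc_code": r.atc_code,
                "cases": r.n11,
                "non_cases": r.n10,
                "total": r.n11 + r.n10,
                "ror": round_half_up(rr.ror),
                "ror_ci_low": round_half_up(rr.ci_low),
                "ror_ci_high": round_half_up(rr.ci_high),
                "ic": round_half_up(ic.ic),
                "ic025": round_half_up(ic.ic025),
                "signal": r.signal,
                "low_expected": r.low_expected,
            }
        )
    return pd.DataFrame(rows)
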