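"""Clinical comparison statistics for carrier vs background cohorts.

Covers the comparisons typically reported alongside a founder-variant
cohort: Welch two-sample t-tests computed directly from published
mean +/- SD summaries, exact/chi-square tests on categorical splits,
CKD-EPI 2009 eGFR with KDIGO G/A staging, and renal survival
(Kaplan-Meier product-limit curves with a two-group log-rank test, backed
by lifelines).

"Independent t-test" is implemented as Welch's unequal-variance form: with
a small carrier group against a population-scale background the Welch
degrees of freedom collapse to n_carrier - 1 and the p-value is driven by
the carrier group's summary alone, which is the regime these cohort tables
live in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from .rare_tagging import ContingencyTable, fisher_exact_2x2


class ZeroVarianceError(ValueError):
    """Both groups have zero variance but different means: t is infinite."""


class SurvivalError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SD summary of one group (n >= 2 for a defined variance)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        return cls(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_two_sided: float


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> WelchResult:
    """Welch's t-test from group summaries.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), Welch-Satterthwaite degrees of
    freedom, two-sided p from Student's t.  Antisymmetric in group order.
    """
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    if v1 + v2 == 0:
        if g1.mean == g2.mean:
            return WelchResult(0.0, float(g1.n + g2.n - 2), 1.0)
        raise ZeroVarianceError(
            "zero variance in both groups with unequal means"
        )
    t = (g1.mean - g2.mean) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return WelchResult(t, df, float(p))


def chi_square_2x2(
    table: ContingencyTable, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 degree of freedom.

    Closed form N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the Yates correction
    subtracts N/2 from |ad-bc| (clamped at zero) when requested.  Any empty
    margin gives a zero expected count and raises.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("zero expected count: a margin of the table is empty")
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(0.0, diff - n / 2)
    stat = n * diff**2 / margins
    return float(stat), float(stats.chi2.sf(stat, df=1))


@dataclass(frozen=True)
class CkdEpiInput:
    creatinine_mg_dl: float
    age: float
    sex: str  # "female" | "male"
    black: bool = False


def ckd_epi_2009(x: CkdEpiInput) -> float:
    """CKD-EPI 2009 estimated GFR in mL/min/1.73 m^2.

    eGFR = 141 * min(Scr/k, 1)^alpha * max(Scr/k, 1)^-1.209 * 0.993^age
           * 1.018 [female] * 1.159 [black],
    k = 0.7 (female) / 0.9 (male), alpha = -0.329 (female) / -0.411 (male).
    The ethnicity coefficient is retained as published in the 2009 equation
    and is flag-controlled (default off).
    """
    if x.creatinine_mg_dl <= 0 or x.age <= 0:
        raise ValueError("creatinine and age must be positive")
    sex = x.sex.lower()
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {x.sex!r}")
    kappa, alpha = (0.7, -0.329) if sex == "female" else (0.9, -0.411)
    ratio = x.creatinine_mg_dl / kappa
    egfr = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209
    egfr *= 0.993**x.age
    if sex == "female":
        egfr *= 1.018
    if x.black:
        egfr *= 1.159
    return egfr


def ckd_stage(
    egfr: float, acr_mg_per_mmol: float | None = None
) -> tuple[str, str | None, bool]:
    """KDIGO G-stage, A-stage and CKD flag.

    G cut-points (eGFR, mL/min/1.73 m^2): >=90 G1, 60-89 G2, 45-59 G3a,
    30-44 G3b, 15-29 G4, <15 G5.  A cut-points (ACR, mg/mmol): <3 A1,
    3-30 A2, >30 A3.  The CKD flag is eGFR < 60 or albuminuria >= A2; the
    KDIGO 3-month duration criterion is the caller's responsibility.
    """
    if egfr < 0:
        raise ValueError("eGFR must be >= 0")
    if egfr >= 90:
        g = "G1"
    elif egfr >= 60:
        g = "G2"
    elif egfr >= 45:
        g = "G3a"
    elif egfr >= 30:
        g = "G3b"
    elif egfr >= 15:
        g = "G4"
    else:
        g = "G5"
    a: str | None = None
    if acr_mg_per_mmol is not None:
        if acr_mg_per_mmol < 3:
            a = "A1"
        elif acr_mg_per_mmol <= 30:
            a = "A2"
        else:
            a = "A3"
    ckd = egfr < 60 or (a is not None and a != "A1")
    return g, a, ckd


@dataclass(frozen=True)
class SurvivalRecord:
    """Time-to-event record: renal survival is age at the start of renal
    replacement therapy, censored at last follow-up otherwise."""

    sample: str
    time: float
    event: bool
    group: str = ""

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be > 0")


@dataclass
class KMResult:
    """Product-limit curve: right-continuous steps at event times."""

    times: np.ndarray
    survival: np.ndarray
    median: float | None

    def at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(records: list[SurvivalRecord]) -> KMResult:
    """Kaplan-Meier product-limit estimate with S(0) = 1.

    The median is the first time with S(t) <= 0.5, None if the curve never
    reaches 0.5 (e.g. everything censored).
    """
    if not records:
        raise SurvivalError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(
        [r.time for r in records], event_observed=[r.event for r in records]
    )
    surv = kmf.survival_function_["KM_estimate"]
    times = surv.index.to_numpy(dtype=float)
    values = surv.to_numpy(dtype=float)
    med = kmf.median_survival_time_
    return KMResult(
        times=times,
        survival=values,
        median=None if math.isinf(med) else float(med),
    )


def logrank(records: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test (observed minus expected, hypergeometric
    variance at each distinct event time); p from chi-square with 1 df.

    Records must carry exactly two distinct group labels and at least one
    event overall.
    """
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise SurvivalError(f"log-rank needs exactly 2 groups, got {groups}")
    if not any(r.event for r in records):
        raise SurvivalError("log-rank undefined with no events")
    g1 = [r for r in records if r.group == groups[0]]
    g2 = [r for r in records if r.group == groups[1]]
    res = _lifelines_logrank(
        [r.time for r in g1],
        [r.time for r in g2],
        event_observed_A=[r.event for r in g1],
        event_observed_B=[r.event for r in g2],
    )
    return float(res.test_statistic), float(res.p_value)


def survival_records_from_frame(
    pheno: pd.DataFrame, group_col: str = "sex"
) -> list[SurvivalRecord]:
    """Build survival records from a phenotype table with columns
    sample / age / event (and a grouping column)."""
    return [
        SurvivalRecord(
            sample=str(row["sample"]),
            time=float(row["age"]),
            event=bool(row["event"]),
            group=str(row[group_col]),
        )
        for _, row in pheno.iterrows()
    ]


def clinical_comparison(
    pheno: pd.DataFrame,
    carrier_ids: list[str],
    continuous: list[str] = ("age", "sbp", "dbp", "creatinine_mg_dl", "acr", "urate"),
    categorical: list[str] = ("sex", "gout"),
) -> pd.DataFrame:
    """Carrier-vs-background comparison table from a per-sample phenotype
    frame: Welch t for continuous columns, Fisher's exact for categorical.

    Returns one row per variable with group summaries and the p-value,
    mirroring the layout of a cohort characteristics table.
    """
    carrier_set = set(carrier_ids)
    is_carrier = pheno["sample"].astype(str).isin(carrier_set)
    rows = []
    for col in continuous:
        if col not in pheno.columns:
            continue
        g1 = GroupSummary.from_values(pheno.loc[is_carrier, col])
        g2 = GroupSummary.from_values(pheno.loc[~is_carrier, col])
        res = welch_t_from_summary(g1, g2)
        rows.append(
            {
                "variable": col,
                "carrier": f"{g1.mean:.1f}±{g1.sd:.1f}",
                "background": f"{g2.mean:.1f}±{g2.sd:.1f}",
                "test": "welch_t",
                "p": res.p_two_sided,
            }
        )
    for col in categorical:
        if col not in pheno.columns:
            continue
        values = pheno[col]
        level = sorted(values.unique())[0]
        a = int(((values == level) & is_carrier).sum())
        b = int(((values != level) & is_carrier).sum())
        c = int(((values == level) & ~is_carrier).sum())
        d = int(((values != level) & ~is_carrier).sum())
        res = fisher_exact_2x2(ContingencyTable(a, b, c, d))
        rows.append(
            {
                "variable": f"{col}={level}",
                "carrier": f"{a}/{a + b}",
                "background": f"{c}/{c + d}",
                "test": "fisher_exact",
                "p": res.p_two_sided,
            }
        )
    return pd.DataFrame(rows)
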