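"""Outcome definitions and diagnostic-accuracy statistics.

Case definitions
----------------
Iron deficiency (ID) follows the serum-marker criteria: ferritin
SF ≤ 30 µg/L; or SF ≤ 100 µg/L under an inflammatory syndrome; or
transferrin saturation TPS ≤ 16% with SF ≤ 300 µg/L.  "Blue sclera" is a
grade ≥ 3 (definite or striking) for a single rater, or at least two of
three raters at grade ≥ 3 under the consensus rule.  Anemia is
hemoglobin ≤ 12 g/dL in women and ≤ 13 g/dL in men.

Statistics
----------
Sensitivity, specificity and predictive values with exact Clopper–Pearson
intervals; likelihood ratios with Simel log-method intervals; Pearson χ²
(no continuity correction) falling back to Fisher's exact test when any
expected count is below 5; Fleiss' κ for the three raters; Lin's
concordance correlation coefficient; and a maximum-likelihood logistic
regression giving covariate-adjusted odds ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats import inter_rater
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "classify_iron_status",
    "classify_blue",
    "classify_anemia",
    "ContingencyTable2x2",
    "build_contingency",
    "clopper_pearson",
    "Estimate",
    "DiagnosticSummary",
    "diagnostic_metrics",
    "AssociationTest",
    "association_test",
    "fleiss_kappa",
    "agreement_band",
    "lin_ccc",
    "AdjustedOddsRatio",
    "SeparationError",
    "logistic_adjusted_or",
    "CRP_INFLAMMATION_THRESHOLD",
]

# Inflammation is operationalized as CRP > 5 mg/L when no explicit
# inflammatory-syndrome flag is available.
CRP_INFLAMMATION_THRESHOLD = 5.0


def classify_iron_status(
    ferritin: float,
    tps: float | None = None,
    inflammation: bool | None = None,
    crp: float | None = None,
) -> bool:
    """True iff the serum markers meet any iron-deficiency criterion.

    ID iff SF ≤ 30, or (inflammation and SF ≤ 100), or
    (TPS ≤ 16 and SF ≤ 300).  A missing TPS leaves only the ferritin
    clauses; a missing inflammation flag is derived from CRP when given,
    and taken as absent otherwise.
    """
    if ferritin is None or (isinstance(ferritin, float) and math.isnan(ferritin)):
        raise ValueError("ferritin is required to assess iron stores")
    if ferritin < 0:
        raise ValueError("ferritin must be nonnegative")
    if inflammation is None:
        inflammation = crp is not None and not math.isnan(crp) \
            and crp > CRP_INFLAMMATION_THRESHOLD
    if ferritin <= 30:
        return True
    if inflammation and ferritin <= 100:
        return True
    if tps is not None and not (isinstance(tps, float) and math.isnan(tps)):
        if tps <= 16 and ferritin <= 300:
            return True
    return False


def classify_blue(grades: Sequence[int], rule: str) -> bool:
    """Dichotomize the three ordinal grades into blue / not blue.

    ``rule`` is ``"r1"``/``"r2"``/``"r3"`` (that rater grades ≥ 3) or
    ``"consensus"`` (at least two raters grade ≥ 3).
    """
    grades = [int(g) for g in grades]
    if len(grades) != 3 or any(g not in (1, 2, 3, 4) for g in grades):
        raise ValueError("expected three grades, each in 1..4")
    if rule == "consensus":
        return sum(g >= 3 for g in grades) >= 2
    if rule in ("r1", "r2", "r3"):
        return grades[int(rule[1]) - 1] >= 3
    raise ValueError(f"unknown rule {rule!r}; expected r1, r2, r3 or consensus")


def classify_anemia(hemoglobin: float, sex: str) -> bool:
    """Anemia: Hb ≤ 12 g/dL for women, ≤ 13 g/dL for men (inclusive)."""
    if hemoglobin is None or hemoglobin <= 0:
        raise ValueError("hemoglobin must be positive")
    if sex == "F":
        return hemoglobin <= 12.0
    if sex == "M":
        return hemoglobin <= 13.0
    raise ValueError(f"unknown sex {sex!r}; expected 'M' or 'F'")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Index test (rows: positive/negative) × ID status (cols: ID/NID)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if sum(counts) < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


def build_contingency(
    cohort: pd.DataFrame,
    index_rule: str,
    reference: str = "biomarker",
) -> ContingencyTable2x2:
    """Cross-classify an index rule against ID status over a cohort table.

    ``reference="biomarker"`` applies :func:`classify_iron_status` to the
    serum columns; ``reference="true"`` uses the simulation ground-truth
    column ``true_id`` (synthetic cohorts only).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if reference == "true":
        disease = cohort["true_id"].to_numpy(dtype=bool)
    elif reference == "biomarker":
        disease = np.array([
            classify_iron_status(
                row.ferritin_ug_l,
                tps=getattr(row, "tps_pct", None),
                crp=getattr(row, "crp_mg_l", None),
            )
            for row in cohort.itertuples()
        ])
    else:
        raise ValueError("reference must be 'biomarker' or 'true'")
    positive = np.array([
        classify_blue(g, index_rule)
        for g in cohort[["grade_r1", "grade_r2", "grade_r3"]].to_numpy()
    ])
    return ContingencyTable2x2(
        tp=int((positive & disease).sum()),
        fp=int((positive & ~disease).sum()),
        fn=int((~positive & disease).sum()),
        tn=int((~positive & ~disease).sum()),
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (beta-quantile) binomial confidence interval for k/n."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


class Estimate(NamedTuple):
    """A point estimate with its two-sided confidence bounds."""

    point: float
    lower: float
    upper: float


@dataclass(frozen=True)
class DiagnosticSummary:
    """The 2×2 metric battery with 95% intervals.

    Entries are ``None`` when a zero denominator makes the quantity (or
    its Simel interval) non-computable — e.g. NPV when no patient tested
    negative.
    """

    sensitivity: Estimate | None
    specificity: Estimate | None
    ppv: Estimate | None
    npv: Estimate | None
    lr_pos: Estimate | None
    lr_neg: Estimate | None
    prevalence: float
    table: ContingencyTable2x2


def _proportion(k: int, n: int, level: float) -> Estimate | None:
    if n == 0:
        return None
    lo, hi = clopper_pearson(k, n, level)
    return Estimate(k / n, lo, hi)


def diagnostic_metrics(
    table: ContingencyTable2x2, level: float = 0.95
) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV, NPV and likelihood ratios with CIs.

    Proportions carry exact Clopper–Pearson intervals.  LR+ uses the Simel
    log method: exp(ln LR ± z·√((1−sens)/tp + spec/fp)); LR− analogously
    with √(sens/fn + (1−spec)/tn).
    """
    t = table
    z = stats.norm.ppf(0.5 + level / 2)
    sens = _proportion(t.tp, t.tp + t.fn, level)
    spec = _proportion(t.tn, t.tn + t.fp, level)
    ppv = _proportion(t.tp, t.tp + t.fp, level)
    npv = _proportion(t.tn, t.tn + t.fn, level)

    lr_pos = lr_neg = None
    if sens is None or spec is None:
        return DiagnosticSummary(
            sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
            lr_pos=None, lr_neg=None, prevalence=t.prevalence, table=t,
        )
    if t.fp > 0 and t.tp > 0:
        point = sens.point / (1.0 - spec.point)
        se = math.sqrt((1 - sens.point) / t.tp + spec.point / t.fp)
        lr_pos = Estimate(point, point * math.exp(-z * se), point * math.exp(z * se))
    if t.tn > 0 and t.fn > 0:
        point = (1.0 - sens.point) / spec.point
        se = math.sqrt(sens.point / t.fn + (1 - spec.point) / t.tn)
        lr_neg = Estimate(point, point * math.exp(-z * se), point * math.exp(z * se))
    return DiagnosticSummary(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        lr_pos=lr_pos, lr_neg=lr_neg,
        prevalence=t.prevalence, table=t,
    )


class AssociationTest(NamedTuple):
    name: str
    statistic: float | None
    p_value: float


def association_test(table: ContingencyTable2x2) -> AssociationTest:
    """Pearson χ² (no continuity correction), or Fisher's exact test.

    Fisher fires whenever any expected count falls below 5; the result
    names the test that was used.  Degenerate margins are rejected.
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("association test undefined for a zero margin")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / table.total
    if np.all(expected >= 5):
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
        return AssociationTest("chi2", float(chi2), float(p))
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return AssociationTest("fisher", None, float(p))


def fleiss_kappa(
    ratings: np.ndarray | pd.DataFrame,
    categories: Sequence[int] | None = None,
) -> float:
    """Fleiss' κ for subjects × raters categorical ratings.

    ``ratings`` has one row per subject and one column per rater; every
    subject must be rated by every rater.  ``categories`` fixes the
    category set (useful when some categories are unobserved).
    """
    ratings = np.asarray(ratings)
    if ratings.ndim != 2 or ratings.shape[0] < 2:
        raise ValueError("need a 2-D ratings array with at least 2 subjects")
    if categories is None:
        categories = np.unique(ratings)
    counts = np.stack(
        [(ratings == c).sum(axis=1) for c in categories], axis=1
    )
    return float(inter_rater.fleiss_kappa(counts, method="fleiss"))


def agreement_band(value: float) -> str:
    """Qualitative agreement band for κ or concordance coefficients."""
    if value <= 0.20:
        return "poor"
    if value <= 0.40:
        return "fair"
    if value <= 0.60:
        return "moderate"
    if value <= 0.80:
        return "good"
    return "very good"


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ccc = 2·cov(x,y) / (var x + var y + (mean x − mean y)²), penalizing
    both decorrelation and location/scale shift; symmetric in x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D arrays with n >= 2")
    vx, vy = x.var(), y.var()  # population (1/n) moments
    if vx == 0 or vy == 0:
        raise ValueError("concordance undefined for constant input")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


class SeparationError(RuntimeError):
    """Complete separation: the logistic MLE does not exist."""


@dataclass(frozen=True)
class AdjustedOddsRatio:
    """Exposure odds ratio from a covariate-adjusted logistic regression."""

    or_point: float
    ci95: tuple[float, float]
    coefficient: float
    std_err: float
    covariates: tuple[str, ...]
    converged: bool


def logistic_adjusted_or(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: Sequence[str] = ("age", "sex", "hb_g_dl", "crp_mg_l"),
    level: float = 0.95,
) -> AdjustedOddsRatio:
    """Adjusted odds ratio for ``exposure`` on ``outcome`` by ML logit.

    Fits outcome ~ exposure + covariates by Newton-scored maximum
    likelihood; ``sex`` is encoded M=1.  Returns exp(coefficient) with a
    Wald interval.  Complete separation raises :class:`SeparationError`
    instead of silently diverging.
    """
    y = cohort[outcome].astype(float).to_numpy()
    X = pd.DataFrame(index=cohort.index)
    X[exposure] = cohort[exposure].astype(float)
    for cov in covariates:
        if cov == "sex":
            X["sex"] = (cohort["sex"] == "M").astype(float)
        else:
            X[cov] = cohort[cov].astype(float)
    X = sm.add_constant(X, has_constant="add")
    if len(cohort) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    try:
        fit = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=100, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            "complete separation (or singular information) in logistic fit"
        ) from exc
    if not fit.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit failed to converge (quasi-separation?)")
    coef = float(fit.params[exposure])
    se = float(fit.bse[exposure])
    z = stats.norm.ppf(0.5 + level / 2)
    return AdjustedOddsRatio(
        or_point=math.exp(coef),
        ci95=(math.exp(coef - z * se), math.exp(coef + z * se)),
        coefficient=coef,
        std_err=se,
        covariates=tuple(covariates),
        converged=True,
    )
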