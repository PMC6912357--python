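"""Synthetic patient cohorts with known diagnostic structure.

Each simulated patient carries a true iron-deficiency (ID) status, iron
and inflammation biomarkers drawn from per-arm distributions, a latent
scleral blueness β, three ordinal rater grades (1 absent … 4 striking)
produced by thresholding β under independent rater noise, and
blue-percentile (BP) scores for the three delineation methods obtained
through an affine shortcut BP = a + b·β + noise, so cohort-scale
diagnostics can be exercised without rendering images.

The rater model is analytically calibrated: given a target (sensitivity,
specificity) operating point, :func:`calibrate_rater` solves for the
grade threshold and rater noise that achieve it exactly in the limit of
large cohorts, which is what the recovery tests check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "LogNormalSpec",
    "RaterModel",
    "CohortParams",
    "calibrate_rater",
    "simulate_cohort",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "patient_id", "age", "sex", "ferritin_ug_l", "tps_pct", "crp_mg_l",
    "hb_g_dl", "iris_class", "grade_r1", "grade_r2", "grade_r3",
    "bp_fs", "bp_ms", "bp_sas",
]

# Latent blueness β | arm ~ Normal(mean, sd), clipped to [0, 1].  The means
# are set so the BP shortcut below lands on group means near 29 (no ID) and
# 31 (ID), the range seen in scored photographs.
BETA_MEAN_NID = 0.35
BETA_MEAN_ID = 0.65
BETA_SD = 0.12

# BP shortcut: BP = a + b·β + Normal(0, sd), independently per method.
BP_INTERCEPT = 27.0
BP_SLOPE = 6.0
BP_NOISE_SD = 1.5


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal with a stated median and log-scale dispersion."""

    median: float
    sigma: float

    def __post_init__(self) -> None:
        if self.median <= 0 or self.sigma <= 0:
            raise ValueError("median and sigma must be positive")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(np.log(self.median), self.sigma, size=n))


@dataclass(frozen=True)
class RaterModel:
    """One rater: grades by thresholding β + Normal(0, noise_sd).

    The signal s = β + ε is mapped to grades with a band of half-width
    ``grade_halfwidth`` around the blue threshold: grade 4 if
    s ≥ threshold + g, 3 if s ≥ threshold, 2 if s ≥ threshold − g, else 1.
    "Blue" (grade ≥ 3) therefore means s ≥ threshold.
    """

    threshold: float
    noise_sd: float
    grade_halfwidth: float = 0.15

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("rater threshold must be finite")
        if self.noise_sd < 0 or self.grade_halfwidth <= 0:
            raise ValueError("noise_sd must be >= 0 and grade_halfwidth > 0")

    def grade(self, beta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        s = beta + rng.normal(0.0, self.noise_sd, size=beta.shape)
        g = self.grade_halfwidth
        return np.select(
            [s >= self.threshold + g, s >= self.threshold, s >= self.threshold - g],
            [4, 3, 2],
            default=1,
        ).astype(int)

    def operating_point(
        self, beta_mean_id: float = BETA_MEAN_ID, beta_mean_nid: float = BETA_MEAN_NID,
        beta_sd: float = BETA_SD,
    ) -> tuple[float, float]:
        """Analytic (sensitivity, specificity) against true ID status."""
        sd_total = float(np.hypot(beta_sd, self.noise_sd))
        sens = float(norm.sf(self.threshold, loc=beta_mean_id, scale=sd_total))
        spec = float(norm.cdf(self.threshold, loc=beta_mean_nid, scale=sd_total))
        return sens, spec


def calibrate_rater(
    sensitivity: float,
    specificity: float,
    beta_mean_id: float = BETA_MEAN_ID,
    beta_mean_nid: float = BETA_MEAN_NID,
    beta_sd: float = BETA_SD,
    grade_halfwidth: float = 0.15,
) -> RaterModel:
    """Solve for the rater threshold and noise hitting a target operating point.

    With s = β + ε and per-arm β means μ1 (ID) and μ0 (no ID) sharing total
    sd σ_t, the target point fixes σ_t = (μ1 − μ0)/(z_sens + z_spec) and the
    threshold c = μ0 + z_spec·σ_t.  Requires z_sens + z_spec > 0 (a
    better-than-chance rater) and σ_t ≥ β's own sd.
    """
    z_sens = norm.ppf(sensitivity)
    z_spec = norm.ppf(specificity)
    if z_sens + z_spec <= 0:
        raise ValueError("target operating point must be better than chance")
    sd_total = (beta_mean_id - beta_mean_nid) / (z_sens + z_spec)
    if sd_total < beta_sd:
        raise ValueError(
            "target operating point too sharp for the latent blueness spread"
        )
    noise_sd = float(np.sqrt(sd_total**2 - beta_sd**2))
    threshold = float(beta_mean_nid + z_spec * sd_total)
    return RaterModel(threshold=threshold, noise_sd=noise_sd,
                      grade_halfwidth=grade_halfwidth)


def _default_raters() -> tuple[RaterModel, ...]:
    # Operating points of the three physicians in the pilot cohort.
    return (
        calibrate_rater(0.608, 0.688),
        calibrate_rater(0.451, 0.813),
        calibrate_rater(0.294, 0.938),
    )


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of a synthetic suspected-ID inpatient cohort.

    Biomarker defaults emulate a hospital population referred for suspected
    iron deficiency: three quarters truly iron-deficient, ferritin medians
    far apart between arms, lower transferrin saturation and hemoglobin in
    the ID arm, and a female-predominant ID arm.
    """

    n_patients: int = 200
    id_prevalence: float = 51 / 67
    ferritin_id: LogNormalSpec = LogNormalSpec(12.0, 0.6)
    ferritin_nid: LogNormalSpec = LogNormalSpec(180.0, 0.7)
    tps_id: LogNormalSpec = LogNormalSpec(8.0, 0.35)
    tps_nid: LogNormalSpec = LogNormalSpec(25.0, 0.30)
    crp: LogNormalSpec = LogNormalSpec(5.0, 0.9)
    hb_mean_id: float = 10.4
    hb_mean_nid: float = 12.6
    hb_sd: float = 1.7
    hb_male_shift: float = 0.8
    male_prob_id: float = 0.37
    male_prob_nid: float = 0.69
    age_mean_id: float = 63.0
    age_mean_nid: float = 52.0
    age_sd: float = 19.0
    light_iris_prob: float = 0.35
    beta_mean_id: float = BETA_MEAN_ID
    beta_mean_nid: float = BETA_MEAN_NID
    beta_sd: float = BETA_SD
    raters: tuple[RaterModel, ...] = field(default_factory=_default_raters)
    bp_intercept: float = BP_INTERCEPT
    bp_slope: float = BP_SLOPE
    bp_noise_sd: float = BP_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        if not 0.0 < self.id_prevalence < 1.0:
            raise ValueError("id_prevalence must lie in (0, 1)")
        if self.beta_sd <= 0 or self.hb_sd <= 0 or self.age_sd <= 0:
            raise ValueError("dispersion parameters must be positive")
        if len(self.raters) != 3:
            raise ValueError("exactly three raters are modeled")


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a cohort table; deterministic given ``params.seed``.

    Returns one row per patient with the standard cohort columns plus the
    simulation-only ground truth ``true_id`` and ``latent_blueness``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    is_id = rng.random(n) < params.id_prevalence

    def per_arm(id_spec: LogNormalSpec, nid_spec: LogNormalSpec) -> np.ndarray:
        out = np.empty(n)
        out[is_id] = id_spec.draw(rng, int(is_id.sum()))
        out[~is_id] = nid_spec.draw(rng, int((~is_id).sum()))
        return out

    ferritin = per_arm(params.ferritin_id, params.ferritin_nid)
    tps = np.clip(per_arm(params.tps_id, params.tps_nid), 0.0, 100.0)
    crp = params.crp.draw(rng, n)
    male = rng.random(n) < np.where(is_id, params.male_prob_id, params.male_prob_nid)
    hb = rng.normal(
        np.where(is_id, params.hb_mean_id, params.hb_mean_nid)
        + params.hb_male_shift * male,
        params.hb_sd,
    )
    age = np.clip(
        rng.normal(np.where(is_id, params.age_mean_id, params.age_mean_nid),
                   params.age_sd),
        18.0, 100.0,
    )
    beta = np.clip(
        rng.normal(np.where(is_id, params.beta_mean_id, params.beta_mean_nid),
                   params.beta_sd),
        0.0, 1.0,
    )
    grades = {f"grade_r{k + 1}": rater.grade(beta, rng)
              for k, rater in enumerate(params.raters)}
    bp = {
        f"bp_{m}": params.bp_intercept + params.bp_slope * beta
        + rng.normal(0.0, params.bp_noise_sd, size=n)
        for m in ("fs", "ms", "sas")
    }
    return pd.DataFrame({
        "patient_id": [f"P{i:05d}" for i in range(n)],
        "age": np.round(age, 1),
        "sex": np.where(male, "M", "F"),
        "ferritin_ug_l": ferritin,
        "tps_pct": tps,
        "crp_mg_l": crp,
        "hb_g_dl": hb,
        "iris_class": np.where(rng.random(n) < params.light_iris_prob,
                               "light", "dark"),
        **grades,
        **bp,
        "true_id": is_id,
        "latent_blueness": beta,
    })
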