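"""Study-level model tying the cohort analysis together.

:class:`BlueScleraStudy` is constructed from a cohort table (one row per
patient: serum markers, demographics, three rater grades and optional
per-method BP scores); ``fit()`` runs the whole diagnostic-accuracy
analysis and returns a :class:`StudyResults` carrying 2×2 tables, the
metric battery with exact CIs, association tests, inter-rater agreement,
between-method concordance, ROC analyses and covariate-adjusted odds
ratios, with a ``summary()`` table and JSON/markdown export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as dx
from .roc import ROCAnalysis, roc_analysis

__all__ = ["BlueScleraStudy", "StudyResults"]

_RULES = ("r1", "r2", "r3", "consensus")
_BP_METHODS = ("fs", "ms", "sas")


class BlueScleraStudy:
    """Diagnostic-accuracy study of blue sclera for iron deficiency.

    Parameters
    ----------
    cohort : DataFrame
        Standard cohort columns (``patient_id, age, sex, ferritin_ug_l,
        tps_pct, crp_mg_l, hb_g_dl, iris_class, grade_r1..r3`` and optional
        ``bp_fs, bp_ms, bp_sas``).
    reference : {"biomarker", "true"}
        Disease reference: serum-marker classification, or the simulation
        ground-truth column ``true_id`` for synthetic cohorts.
    """

    def __init__(self, cohort: pd.DataFrame, reference: str = "biomarker"):
        if len(cohort) < 2:
            raise ValueError("a study needs at least 2 patients")
        if reference not in ("biomarker", "true"):
            raise ValueError("reference must be 'biomarker' or 'true'")
        self.cohort = cohort.reset_index(drop=True)
        self.reference = reference

    @classmethod
    def from_csv(cls, path: str | Path, reference: str = "biomarker") -> "BlueScleraStudy":
        from .io import read_cohort_csv

        return cls(read_cohort_csv(path), reference=reference)

    def disease_status(self) -> np.ndarray:
        if self.reference == "true":
            return self.cohort["true_id"].to_numpy(dtype=bool)
        return np.array([
            dx.classify_iron_status(
                row.ferritin_ug_l,
                tps=getattr(row, "tps_pct", None),
                crp=getattr(row, "crp_mg_l", None),
            )
            for row in self.cohort.itertuples()
        ])

    def fit(
        self,
        rules: tuple[str, ...] = _RULES,
        bp_methods: tuple[str, ...] = _BP_METHODS,
        ci_level: float = 0.95,
        adjust_covariates: tuple[str, ...] = ("age", "sex", "hb_g_dl", "crp_mg_l"),
    ) -> "StudyResults":
        """Run the full analysis and return the results object."""
        cohort = self.cohort
        disease = self.disease_status()

        tables, metrics, association, adjusted = {}, {}, {}, {}
        for rule in rules:
            table = dx.build_contingency(
                cohort.assign(true_id=disease), rule, reference="true"
            )
            tables[rule] = table
            metrics[rule] = dx.diagnostic_metrics(table, level=ci_level)
            try:
                association[rule] = dx.association_test(table)
            except ValueError:
                association[rule] = None
            if all(c in cohort.columns for c in adjust_covariates if c != "sex"):
                blue = np.array([
                    dx.classify_blue(g, rule)
                    for g in cohort[["grade_r1", "grade_r2", "grade_r3"]].to_numpy()
                ])
                frame = cohort.assign(_blue=blue.astype(float), _id=disease.astype(float))
                try:
                    adjusted[rule] = dx.logistic_adjusted_or(
                        frame, "_blue", "_id", covariates=adjust_covariates,
                        level=ci_level,
                    )
                except (dx.SeparationError, ValueError):
                    adjusted[rule] = None

        grades = cohort[["grade_r1", "grade_r2", "grade_r3"]].to_numpy()
        kappa_binary = dx.fleiss_kappa((grades >= 3).astype(int), categories=(0, 1))
        kappa_grades = dx.fleiss_kappa(grades, categories=(1, 2, 3, 4))

        present = [m for m in bp_methods if f"bp_{m}" in cohort.columns
                   and cohort[f"bp_{m}"].notna().all()]
        ccc = {}
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                ccc[f"{a}_vs_{b}"] = dx.lin_ccc(cohort[f"bp_{a}"], cohort[f"bp_{b}"])
        rocs = {}
        for m in present:
            if 0 < disease.sum() < len(disease):
                rocs[m] = roc_analysis(cohort[f"bp_{m}"].to_numpy(), disease,
                                       level=ci_level)
        return StudyResults(
            n_patients=len(cohort),
            prevalence=float(disease.mean()),
            tables=tables, metrics=metrics, association=association,
            adjusted_or=adjusted, fleiss_kappa_binary=kappa_binary,
            fleiss_kappa_grades=kappa_grades, lin_ccc=ccc, roc=rocs,
            ci_level=ci_level,
        )


@dataclass(frozen=True)
class StudyResults:
    """Fitted diagnostic-accuracy results; see :class:`BlueScleraStudy`."""

    n_patients: int
    prevalence: float
    tables: dict[str, dx.ContingencyTable2x2]
    metrics: dict[str, dx.DiagnosticSummary]
    association: dict[str, dx.AssociationTest | None]
    adjusted_or: dict[str, dx.AdjustedOddsRatio | None]
    fleiss_kappa_binary: float
    fleiss_kappa_grades: float
    lin_ccc: dict[str, float]
    roc: dict[str, ROCAnalysis]
    ci_level: float = 0.95

    def summary(self) -> str:
        """Human-readable summary table (percent scale, 95% CIs)."""
        lines = [
            "Blue sclera vs iron deficiency — diagnostic accuracy",
            "=" * 68,
            f"Patients: {self.n_patients}   ID prevalence: {100 * self.prevalence:.1f}%",
            "",
            f"{'rule':<10}{'sens %':>14}{'spec %':>14}{'PPV %':>14}{'NPV %':>14}"
            f"{'LR+':>10}",
        ]
        for rule, m in self.metrics.items():
            def pct(e: dx.Estimate | None) -> str:
                if e is None:
                    return "n/c"
                return f"{100 * e.point:.1f} ({100 * e.lower:.1f};{100 * e.upper:.1f})"

            lr = f"{m.lr_pos.point:.2f}" if m.lr_pos else "n/c"
            lines.append(
                f"{rule:<10}{pct(m.sensitivity):>14}{pct(m.specificity):>14}"
                f"{pct(m.ppv):>14}{pct(m.npv):>14}{lr:>10}"
            )
        lines.append("")
        lines.append(
            f"Fleiss kappa (blue/not blue): {self.fleiss_kappa_binary:.3f} "
            f"[{dx.agreement_band(self.fleiss_kappa_binary)}]   "
            f"(4-grade: {self.fleiss_kappa_grades:.3f})"
        )
        for pair, value in self.lin_ccc.items():
            lines.append(f"Lin CCC {pair}: {value:.3f} [{dx.agreement_band(value)}]")
        for method, r in self.roc.items():
            y = r.optimal["youden"]
            lines.append(
                f"ROC {method.upper()}: AUC {r.auc:.2f} "
                f"({r.auc_ci95[0]:.2f};{r.auc_ci95[1]:.2f}), Youden threshold "
                f"{y.threshold:.1f} (sens {100 * y.sensitivity:.1f}%, "
                f"spec {100 * y.specificity:.1f}%)"
            )
        for rule, aor in self.adjusted_or.items():
            if aor is not None:
                lines.append(
                    f"Adjusted OR ({rule}): {aor.or_point:.2f} "
                    f"({aor.ci95[0]:.2f};{aor.ci95[1]:.2f})"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready nested dict of every computed quantity."""

        def est(e: dx.Estimate | None):
            return None if e is None else {
                "point": e.point, "lower": e.lower, "upper": e.upper,
            }

        out = {
            "n_patients": self.n_patients,
            "prevalence": self.prevalence,
            "ci_level": self.ci_level,
            "rules": {},
            "fleiss_kappa_binary": self.fleiss_kappa_binary,
            "fleiss_kappa_grades": self.fleiss_kappa_grades,
            "lin_ccc": self.lin_ccc,
            "roc": {},
        }
        for rule, m in self.metrics.items():
            t = self.tables[rule]
            assoc = self.association.get(rule)
            aor = self.adjusted_or.get(rule)
            out["rules"][rule] = {
                "table": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn},
                "sensitivity": est(m.sensitivity),
                "specificity": est(m.specificity),
                "ppv": est(m.ppv),
                "npv": est(m.npv),
                "lr_pos": est(m.lr_pos),
                "lr_neg": est(m.lr_neg),
                "association": None if assoc is None else {
                    "test": assoc.name, "statistic": assoc.statistic,
                    "p_value": assoc.p_value,
                },
                "adjusted_or": None if aor is None else {
                    "or": aor.or_point, "ci95": list(aor.ci95),
                    "covariates": list(aor.covariates),
                },
            }
        for method, r in self.roc.items():
            out["roc"][method] = {
                "auc": r.auc, "auc_ci95": list(r.auc_ci95),
                "n_pos": r.n_pos, "n_neg": r.n_neg,
                "optimal": {
                    name: {
                        "threshold": o.threshold,
                        "sensitivity": o.sensitivity,
                        "specificity": o.specificity,
                    }
                    for name, o in r.optimal.items()
                },
            }
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def plot_roc(self, method: str, ax=None):
        """Plot one method's ROC curve with its Youden point marked."""
        import matplotlib.pyplot as plt

        r = self.roc[method]
        if ax is None:
            _, ax = plt.subplots()
        order = np.argsort(1 - r.specificity)
        ax.plot((1 - r.specificity)[order], r.sensitivity[order],
                drawstyle="steps-post", label=f"{method.upper()} AUC={r.auc:.2f}")
        y = r.optimal["youden"]
        ax.plot(1 - y.specificity, y.sensitivity, "o")
        ax.plot([0, 1], [0, 1], ":", color="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax
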