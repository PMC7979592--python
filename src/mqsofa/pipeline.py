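"""End-to-end validation pipeline: score, stratify, evaluate, report.

``run_validation`` executes the full analysis in a fixed order — scoring,
joint tabulation, diagnostics at cutoff 2, univariate and age-adjusted
logistic mortality models, Hosmer-Lemeshow calibration, the paired ROC
comparison, three-group reclassification, Kaplan-Meier with pairwise
log-rank tests, and survivor length-of-stay tests — and collects everything
in an :class:`AnalysisReport` with a provenance block, so a seed plus a
parameter set reproduces every number byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.special import expit

from . import __version__
from .cohort_io import (
    ExclusionReport,
    JointScoreTable,
    PatientRecord,
    filter_age_subgroup,
    read_cohort,
    tabulate_joint,
)
from .diagnostics import (
    ConfusionTable,
    chi_square_2x2,
    confusion_from_cohort,
    dichotomized_or,
    metrics,
    reclassification_summary,
    round_half_away,
)
from .scores import RiskGroup, SFBandDialect
from .stats import delong_compare, delong_roc, hosmer_lemeshow, logistic_age_adjusted, logistic_fit
from .survival import km_estimate, logrank_test, los_by_group, survival_inputs
from .synthetic import GeneratorParams, generate_cohort

__all__ = ["AnalysisReport", "run_validation", "render_report"]


@dataclass
class AnalysisReport:
    """All sections of the validation analysis plus provenance."""

    provenance: dict
    cohort_summary: dict
    joint_table: JointScoreTable
    logistic: dict  # per score: univariate and age-adjusted OR rows
    diagnostics: dict  # per score: confusion + metrics + dichotomized OR
    roc: dict  # per score RocResult + DeLong comparison
    reclassification: Any
    survival: dict  # KM curves per group + pairwise log-rank
    los: Any  # LosSummary or skip marker
    skipped: dict = field(default_factory=dict)


def _cohort_summary(records: Sequence[PatientRecord]) -> dict:
    ages_died = [r.age for r in records if r.died]
    ages_disc = [r.age for r in records if not r.died]
    n = len(records)
    n_m = sum(r.sex == "M" for r in records)
    deaths = len(ages_died)
    sex_table = [
        [sum(r.sex == "M" and r.died for r in records), sum(r.sex == "M" and not r.died for r in records)],
        [sum(r.sex == "F" and r.died for r in records), sum(r.sex == "F" and not r.died for r in records)],
    ]
    try:
        sex_chi2, sex_p = chi_square_2x2(sex_table)
    except Exception:
        sex_chi2 = sex_p = float("nan")
    return {
        "n": n,
        "n_male": n_m,
        "n_female": n - n_m,
        "deaths": deaths,
        "mortality_percent": round_half_away(100.0 * deaths / n, 1),
        "age_died_mean": float(np.mean(ages_died)) if ages_died else float("nan"),
        "age_died_sd": float(np.std(ages_died, ddof=1)) if len(ages_died) > 1 else float("nan"),
        "age_discharged_mean": float(np.mean(ages_disc)) if ages_disc else float("nan"),
        "age_discharged_sd": float(np.std(ages_disc, ddof=1)) if len(ages_disc) > 1 else float("nan"),
        "sex_mortality_chi2": sex_chi2,
        "sex_mortality_p": sex_p,
    }


def run_validation(
    cohort_path: str | Path | None = None,
    params: GeneratorParams | None = None,
    subgroup: str = "all",
    dialect: SFBandDialect | str = SFBandDialect.TABLE,
    keep_going: bool = False,
) -> AnalysisReport:
    """Run the full validation on a cohort file or a freshly simulated cohort.

    Exactly one of ``cohort_path`` / ``params`` must be given.  ``subgroup``
    restricts the analysis to an age band (``under70`` / ``over90``) for the
    sensitivity analyses.  With ``keep_going``, a failing stage is recorded
    under ``skipped`` instead of aborting.
    """
    if (cohort_path is None) == (params is None):
        raise ValueError("provide exactly one of cohort_path or params")
    dialect = SFBandDialect(dialect)
    exclusions: ExclusionReport | None = None
    if cohort_path is not None:
        records, exclusions = read_cohort(cohort_path)
        source = {"cohort_path": str(cohort_path)}
    else:
        records = generate_cohort(params)
        source = {
            "generator": {
                "mode": params.mode,
                "seed": params.seed,
                "scale": params.scale,
                "n": params.n,
                "beta1": params.beta1,
                "target_mortality": params.target_mortality,
                "age_beta": params.age_beta,
            }
        }
    records = filter_age_subgroup(records, subgroup)
    if not records:
        raise ValueError(f"no records remain after subgroup filter {subgroup!r}")

    skipped: dict[str, str] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            if not keep_going:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            skipped[name] = str(exc)
            return None

    scores = [r.score(dialect) for r in records]
    y = np.array([1 if r.died else 0 for r in records])
    qsofa = np.array([s.qsofa for s in scores], dtype=float)
    mqsofa = np.array([s.mqsofa for s in scores], dtype=float)
    age = np.array([r.age for r in records], dtype=float)

    joint = stage("tabulate", lambda: tabulate_joint(records, dialect))

    diag = {}
    for name in ("qsofa", "mqsofa"):
        def _diag(name=name):
            ct = confusion_from_cohort(records, name, cutoff=2, dialect=dialect)
            return {"confusion": ct, "metrics": metrics(ct), "odds_ratio": dichotomized_or(ct)}
        out = stage(f"diagnostics_{name}", _diag)
        if out is not None:
            diag[name] = out

    logistic = {}
    for name, vec in (("qsofa", qsofa), ("mqsofa", mqsofa)):
        def _full(vec=vec):
            uni = logistic_fit(y, vec)
            adj = logistic_age_adjusted(y, vec, age)
            fitted = expit(uni.coefficients[0] + uni.coefficients[1] * vec)
            hl = hosmer_lemeshow(y, fitted)
            return {"univariate": uni, "age_adjusted": adj, "hosmer_lemeshow": hl}
        out = stage(f"logistic_{name}", _full)
        if out is not None:
            logistic[name] = out

    def _roc():
        pos_q, neg_q = qsofa[y == 1], qsofa[y == 0]
        pos_m, neg_m = mqsofa[y == 1], mqsofa[y == 0]
        return {
            "qsofa": delong_roc(pos_q, neg_q),
            "mqsofa": delong_roc(pos_m, neg_m),
            "comparison": delong_compare(pos_m, neg_m, pos_q, neg_q),
        }

    roc = stage("roc", _roc) or {}

    reclass = stage(
        "reclassification",
        lambda: reclassification_summary(joint, records, dialect) if joint else None,
    )

    def _survival():
        data = survival_inputs(records, dialect)
        curves = {}
        for g in RiskGroup:
            if any(d.group == g for d in data):
                curves[g.value] = km_estimate(data, g)
        pairs = {}
        groups = [g for g in RiskGroup if g.value in curves]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                key = f"{groups[i].value}_vs_{groups[j].value}"
                pairs[key] = logrank_test(data, [groups[i], groups[j]])
        overall = logrank_test(data, groups) if len(groups) >= 2 else None
        return {"km": curves, "pairwise_logrank": pairs, "overall_logrank": overall}

    surv = stage("survival", _survival) or {}
    los = stage("los", lambda: los_by_group(records, dialect))

    provenance = {
        "version": __version__,
        "sf_band_dialect": dialect.value,
        "subgroup": subgroup,
        **source,
    }
    if exclusions is not None:
        provenance["exclusions"] = {
            "n_input": exclusions.n_input,
            "n_retained": exclusions.n_retained,
            "reasons": dict(exclusions.reasons),
        }

    report = AnalysisReport(
        provenance=provenance,
        cohort_summary=_cohort_summary(records),
        joint_table=joint,
        logistic=logistic,
        diagnostics=diag,
        roc=roc,
        reclassification=reclass,
        survival=surv,
        los=los,
        skipped=skipped,
    )
    return report


def _fmt(x: float | None, nd: int) -> str:
    return "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.{nd}f}"


def _fit_row(fit) -> dict:
    return {
        "or": round_half_away(float(fit.odds_ratios[1]), 2),
        "ci_low": round_half_away(float(fit.or_ci95[1, 0]), 2),
        "ci_high": round_half_away(float(fit.or_ci95[1, 1]), 2),
        "p": float(fit.p_values[1]),
    }


def render_report(report: AnalysisReport, out_dir: str | Path, fmt: str = "csv-bundle") -> list[Path]:
    """Write the report as one file per section (CSV bundle plus a text digest).

    Percentages print to 1 decimal, odds ratios to 2, AUCs to 3; no
    timestamps, so outputs are byte-stable under a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write(name: str, text: str) -> None:
        path = out / name
        path.write_text(text)
        written.append(path)

    write("provenance.json", json.dumps(report.provenance, indent=2, sort_keys=True) + "\n")
    cs = report.cohort_summary
    write(
        "cohort_summary.csv",
        "key,value\n" + "".join(f"{k},{v}\n" for k, v in cs.items()),
    )
    if report.joint_table is not None:
        write("joint_table.csv", report.joint_table.to_frame().to_csv())
    if report.logistic:
        lines = ["score,model,or,ci_low,ci_high,p,hl_stat,hl_df,hl_p"]
        for score, sec in report.logistic.items():
            hl = sec["hosmer_lemeshow"]
            for model in ("univariate", "age_adjusted"):
                row = _fit_row(sec[model])
                lines.append(
                    f"{score},{model},{row['or']:.2f},{row['ci_low']:.2f},"
                    f"{row['ci_high']:.2f},{row['p']:.3g},{hl.statistic:.3f},{hl.df},{hl.p:.3f}"
                )
        write("logistic.csv", "\n".join(lines) + "\n")
    if report.diagnostics:
        lines = ["score,sensitivity,specificity,accuracy,ppv,npv,or,or_ci_low,or_ci_high"]
        txt = ["Diagnostic accuracy at score >= 2 (percent)"]
        txt.append(f"{'':10s}{'Sens':>8s}{'Spec':>8s}{'Acc':>8s}{'PPV':>8s}{'NPV':>8s}")
        for score, sec in report.diagnostics.items():
            pct = sec["metrics"].report_percent
            orr = sec["odds_ratio"]
            lines.append(
                f"{score},{_fmt(pct['sensitivity'],1)},{_fmt(pct['specificity'],1)},"
                f"{_fmt(pct['accuracy'],1)},{_fmt(pct['ppv'],1)},{_fmt(pct['npv'],1)},"
                f"{orr.oddsratio:.1f},{orr.ci95[0]:.1f},{orr.ci95[1]:.1f}"
            )
            txt.append(
                f"{score:10s}"
                + "".join(
                    f"{_fmt(pct[k],1):>8s}"
                    for k in ("sensitivity", "specificity", "accuracy", "ppv", "npv")
                )
            )
        write("diagnostics.csv", "\n".join(lines) + "\n")
        write("diagnostics.txt", "\n".join(txt) + "\n")
    if report.roc:
        lines = ["score,auc,se,ci_low,ci_high"]
        for score in ("qsofa", "mqsofa"):
            if score in report.roc:
                r = report.roc[score]
                lines.append(f"{score},{r.auc:.3f},{r.se:.4f},{r.ci95[0]:.3f},{r.ci95[1]:.3f}")
        cmp_ = report.roc.get("comparison")
        if cmp_ is not None:
            lines.append(f"delong_z,{cmp_.z:.3f},,,")
            lines.append(f"delong_p,{cmp_.p:.3g},,,")
        write("roc.csv", "\n".join(lines) + "\n")
    if report.reclassification is not None:
        rc = report.reclassification
        body = (
            "group,n,deaths,death_rate\n"
            + "".join(
                f"{g},{n},{(rc.deaths_by_group or {}).get(g, '')},"
                f"{_fmt((rc.death_rate_by_group or {}).get(g), 3)}\n"
                for g, n in (
                    ("low", rc.n_low),
                    ("reclassified_high", rc.n_reclassified),
                    ("high", rc.n_high),
                )
            )
            + f"percent_reclassified,{rc.percent_reclassified},,\n"
        )
        write("reclassification.csv", body)
    if report.survival:
        lines = ["group,time,survival,at_risk,events"]
        for g, curve in report.survival.get("km", {}).items():
            for t, s, n_r, d in zip(curve.event_times, curve.survival, curve.at_risk, curve.events):
                lines.append(f"{g},{t:g},{s:.4f},{n_r},{d}")
        write("km_curves.csv", "\n".join(lines) + "\n")
        lines = ["comparison,chi2,df,p"]
        for key, lr in report.survival.get("pairwise_logrank", {}).items():
            lines.append(f"{key},{lr.chi2:.3f},{lr.df},{lr.p:.3g}")
        ov = report.survival.get("overall_logrank")
        if ov is not None:
            lines.append(f"overall,{ov.chi2:.3f},{ov.df},{ov.p:.3g}")
        write("logrank.csv", "\n".join(lines) + "\n")
    if report.los is not None:
        los = report.los
        body = "group,n,median,q1,q3\n" + "".join(
            f"{g},{los.n_per_group[g]},{los.medians[g]:.1f},"
            f"{los.iqrs[g][0]:.1f},{los.iqrs[g][1]:.1f}\n"
            for g in sorted(los.medians)
        )
        body += f"test,{los.test},statistic,{los.statistic:.3f},p={los.p:.3g}\n"
        write("los.csv", body)
    if report.skipped:
        write(
            "skipped.txt",
            "".join(f"skipped: {k}: {v}\n" for k, v in report.skipped.items()),
        )
    return written
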