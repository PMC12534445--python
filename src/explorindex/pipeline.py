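"""End-to-end orchestration: validated data in, structured report out.

Stages run in analysis order — validation, per-individual metrics and the
Exploration Index, bout-level typicality accounting, explorer clustering,
the OLS and Huber regressions of the index on sex, parity and central age,
the bout-level atypicality logistic, and the maternal-ID variance
components / ICC.  Each section of the report is either populated or
explicitly marked skipped with a reason (degenerate inputs never abort the
run).  Re-running on identical inputs and configuration yields
byte-identical JSON; provenance records input hashes, the configuration
and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from .ethogram_data import Dataset, read_dataset
from .exploration_metrics import MetricProfile, compute_metrics, exploration_index
from .explorer_clustering import ClusterResult, partition_explorers
from .inferential_models import (
    ModelFit,
    SeparationError,
    VarianceComponents,
    huber_fit,
    icc_one_way,
    ols_fit,
)
from .typicality_analysis import (
    FrequencyTable,
    TypicalityBreakdown,
    atypicality_logistic,
    category_frequencies,
    typicality_breakdown,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_pipeline", "run_pipeline_on", "render_report"]

logger = logging.getLogger("explorindex")

MIN_CLUSTER_PROFILES = 4


@dataclass
class AnalysisConfig:
    """Tunable knobs of the standard analysis."""

    metric4: str = "rate"  # "rate" | "hours" — fourth index metric
    huber_c: float = 1.345
    k_max: int = 6
    age_cut: float = 4.0
    logistic_unit: str = "bout"  # "bout" | "individual"
    icc_method: str = "reml"  # "reml" | "anova"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)


@dataclass
class AnalysisReport:
    frequency_table: Optional[FrequencyTable] = None
    typicality: Optional[TypicalityBreakdown] = None
    metric_profiles: list[MetricProfile] = field(default_factory=list)
    clusters: Optional[ClusterResult] = None
    logistic_fit: Optional[ModelFit] = None
    ols_fit: Optional[ModelFit] = None
    huber_fit: Optional[ModelFit] = None
    icc: Optional[VarianceComponents] = None
    skipped: dict[str, str] = field(default_factory=dict)  # section -> reason
    provenance: dict[str, Any] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            logger.info("stage %s: done in %.3fs", name, time.perf_counter() - self.t0)
            return False

    return _Timer()


def regression_design(
    ds: Dataset, profiles: list[MetricProfile]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix for Exploration Index ~ sex + parity + central age.

    Treatment contrasts with female and primiparous as reference levels.
    """
    ind = {i.individual_id: i for i in ds.individuals}
    y = np.array([p.exploration_index for p in profiles], dtype=float)
    X = np.column_stack(
        [
            np.ones(len(profiles)),
            [1.0 if ind[p.individual_id].sex == "male" else 0.0 for p in profiles],
            [1.0 if ind[p.individual_id].parity == "multiparous" else 0.0 for p in profiles],
            [p.central_age for p in profiles],
        ]
    )
    return y, X, ["intercept", "sex_male", "parity_multiparous", "central_age"]


def run_pipeline_on(ds: Dataset, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run every analysis stage on an in-memory Dataset."""
    cfg = config or AnalysisConfig()
    report = AnalysisReport()
    report.provenance = {
        "config": asdict(cfg),
        "package_version": __version__,
        "n_bouts": ds.n_bouts,
        "n_individuals": ds.n_individuals,
    }

    with _stage("typicality"):
        if ds.bouts:
            report.frequency_table = category_frequencies(ds)
            report.typicality = typicality_breakdown(ds, age_cut=cfg.age_cut)
        else:
            report.skipped["frequency_table"] = "no bouts"
            report.skipped["typicality"] = "no bouts"

    with _stage("metrics"):
        profiles = compute_metrics(ds)
        hours = {i.individual_id: i.observation_hours for i in ds.individuals}
        if len(profiles) >= 2:
            profiles = exploration_index(profiles, metric4=cfg.metric4, observation_hours=hours)
            report.metric_profiles = profiles
        else:
            report.skipped["metric_profiles"] = (
                f"need >= 2 individuals with bouts, found {len(profiles)}"
            )
        logger.info("metrics: %d profiles from %d bouts", len(profiles), ds.n_bouts)

    with _stage("clustering"):
        if len(report.metric_profiles) >= MIN_CLUSTER_PROFILES:
            report.clusters = partition_explorers(report.metric_profiles, k_max=cfg.k_max)
        else:
            report.skipped["clusters"] = (
                f"clustering requires >= {MIN_CLUSTER_PROFILES} profiled individuals"
            )

    with _stage("logistic"):
        n_atyp = sum(b.typicality == "atypical" for b in ds.bouts)
        n_typ = ds.n_bouts - n_atyp
        if n_atyp >= 2 and n_typ >= 2:
            try:
                report.logistic_fit = atypicality_logistic(ds, unit=cfg.logistic_unit)
            except SeparationError as exc:
                report.skipped["logistic_fit"] = str(exc)
        else:
            report.skipped["logistic_fit"] = "need >= 2 bouts in each typicality class"

    with _stage("regression"):
        if len(report.metric_profiles) >= 6:
            y, X, names = regression_design(ds, report.metric_profiles)
            try:
                report.ols_fit = ols_fit(y, X, names=names)
                report.huber_fit = huber_fit(y, X, c=cfg.huber_c, names=names)
            except np.linalg.LinAlgError as exc:
                report.skipped["regression"] = str(exc)
        else:
            report.skipped["regression"] = "need >= 6 profiled individuals"

    with _stage("icc"):
        profiles = report.metric_profiles
        if profiles:
            ind = {i.individual_id: i for i in ds.individuals}
            groups = [ind[p.individual_id].maternal_id for p in profiles]
            sizes = {g: groups.count(g) for g in set(groups)}
            if len(sizes) >= 2 and any(v >= 2 for v in sizes.values()):
                report.icc = icc_one_way(
                    [p.exploration_index for p in profiles], groups, method=cfg.icc_method
                )
            else:
                report.skipped["icc"] = (
                    "variance components need >= 2 mothers and at least one with >= 2 offspring"
                )
        else:
            report.skipped["icc"] = "no metric profiles"

    return report


def run_pipeline(
    bouts_path: str | Path,
    individuals_path: str | Path,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Read, validate and analyze the two-CSV dataset layout."""
    with _stage("read"):
        ds = read_dataset(bouts_path, individuals_path)
    report = run_pipeline_on(ds, config)
    report.provenance["inputs"] = {
        "bouts": {"path": str(bouts_path), "sha256": _sha256(bouts_path)},
        "individuals": {"path": str(individuals_path), "sha256": _sha256(individuals_path)},
    }
    return report


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _fit_dict(fit: ModelFit) -> dict:
    return {
        "terms": [
            {
                "name": t.name,
                "estimate": t.estimate,
                "std_error": t.std_error,
                "z_value": t.z_value,
                "p_value": t.p_value,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
            }
            for t in fit.terms
        ],
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "scale": fit.scale,
        "method": fit.method,
    }


def report_to_dict(r: AnalysisReport) -> dict:
    out: dict[str, Any] = {"provenance": r.provenance, "skipped": r.skipped}
    if r.frequency_table is not None:
        out["frequency_table"] = {
            "total": r.frequency_table.total,
            "rows": [
                {
                    "category": row.category,
                    "subcategory": row.subcategory,
                    "count": row.count,
                    "proportion_percent": row.proportion_percent,
                }
                for row in r.frequency_table.rows
            ],
        }
    if r.typicality is not None:
        out["typicality"] = asdict(r.typicality)
    if r.metric_profiles:
        out["metric_profiles"] = [
            {
                "individual_id": p.individual_id,
                "total_bouts": p.total_bouts,
                "category_diversity": p.category_diversity,
                "atypical_proportion": p.atypical_proportion,
                "bout_rate": p.bout_rate,
                "age_diversity": p.age_diversity,
                "central_age": p.central_age,
                "z_scores": [float(z) for z in p.z_scores] if p.z_scores is not None else None,
                "exploration_index": p.exploration_index,
            }
            for p in r.metric_profiles
        ]
    if r.clusters is not None:
        c = r.clusters
        out["clusters"] = {
            "k_selected": c.k_selected,
            "assignments": c.assignments,
            "wcss_by_k": {str(k): v for k, v in c.wcss_by_k.items()},
            "cluster_means": c.cluster_means,
            "cluster_sds": c.cluster_sds,
            "cluster_ranges": {k: list(v) for k, v in c.cluster_ranges.items()},
            "cluster_sizes": c.cluster_sizes,
            "u_statistic": c.u_statistic,
            "u_min": c.u_min,
            "p_value": c.p_value,
            "note": c.note,
        }
    for name, fit in (
        ("logistic_fit", r.logistic_fit),
        ("ols_fit", r.ols_fit),
        ("huber_fit", r.huber_fit),
    ):
        if fit is not None:
            out[name] = _fit_dict(fit)
    if r.icc is not None:
        out["icc"] = asdict(r.icc)
    return out


def _md_fit_table(title: str, fit: ModelFit) -> list[str]:
    lines = [
        f"### {title}",
        "",
        "| Predictor | Coefficient | Std. error | z-value | p-value | 95% CI (Lower, Upper) |",
        "|---|---|---|---|---|---|",
    ]
    for t in fit.terms:
        lines.append(
            f"| {t.name} | {t.estimate:.2f} | {t.std_error:.2f} | {t.z_value:.2f} "
            f"| {t.p_value:.3f} | ({t.ci_low:.2f}, {t.ci_high:.2f}) |"
        )
    lines.append("")
    return lines


def render_report(r: AnalysisReport, format: str = "json") -> str:
    """Render the report as schema-stable JSON or human-readable markdown."""
    if format == "json":
        return json.dumps(report_to_dict(r), indent=2, sort_keys=True)
    if format != "markdown":
        raise ValueError("format must be 'json' or 'markdown'")

    lines: list[str] = ["# Exploration analysis report", ""]
    if r.frequency_table is not None:
        lines += [
            "## Object use by category",
            "",
            "| Category | Frequency | Proportion of total (%) |",
            "|---|---|---|",
        ]
        for row in r.frequency_table.rows:
            name = row.category if row.subcategory is None else f"&nbsp;&nbsp;{row.subcategory}"
            lines.append(f"| {name} | {row.count} | {row.proportion_percent:.1f} |")
        lines += [f"| TOTAL | {r.frequency_table.total} | 100 |", ""]
    if r.typicality is not None:
        t = r.typicality
        lines += [
            "## Typicality",
            "",
            f"- typical {t.n_typical}, atypical {t.n_atypical} ({t.pct_atypical:.1f}%)",
            f"- of atypical: omission {t.n_omission} ({t.pct_omission_of_atypical:.1f}%), "
            f"commission {t.n_commission} ({t.pct_commission_of_atypical:.1f}%)",
            f"- atypical share of bouts at ages <= {t.age_cut:g}: {t.young_atypical_pct:.1f}% "
            f"(n={t.n_young}); above: {t.old_atypical_pct:.1f}% (n={t.n_old})",
            "",
        ]
    if r.clusters is not None:
        c = r.clusters
        lines += ["## Explorer clusters", "", f"- k selected by elbow: {c.k_selected}"]
        for nm in sorted(c.cluster_means):
            lines.append(
                f"- {nm}: n={c.cluster_sizes[nm]}, mean={c.cluster_means[nm]:.2f}, "
                f"SD={c.cluster_sds[nm]:.2f}, "
                f"range={c.cluster_ranges[nm][0]:.2f}-{c.cluster_ranges[nm][1]:.2f}"
            )
        if c.u_statistic is not None:
            lines.append(
                f"- Mann-Whitney U (high orientation) = {c.u_statistic:.1f} "
                f"(opposite orientation {c.u_min:.1f}), p = {c.p_value:.4g}"
            )
        lines.append("")
    if r.logistic_fit is not None:
        lines += _md_fit_table("Atypicality ~ age (logistic)", r.logistic_fit)
    if r.ols_fit is not None:
        lines += _md_fit_table("Exploration Index ~ sex + parity + central age (OLS)", r.ols_fit)
    if r.huber_fit is not None:
        lines += _md_fit_table(
            "Exploration Index ~ sex + parity + central age (robust, Huber M)", r.huber_fit
        )
    if r.icc is not None:
        lines += [
            "## Maternal variance components",
            "",
            f"- between-mother variance {r.icc.sigma2_between:.4f}, "
            f"within {r.icc.sigma2_within:.4f}, ICC = {r.icc.icc:.2f} "
            f"({r.icc.method}, {r.icc.n_groups} mothers)",
            "",
        ]
    if r.skipped:
        lines += ["## Skipped sections", ""]
        lines += [f"- {k}: {v}" for k, v in sorted(r.skipped.items())]
        lines.append("")
    return "\n".join(lines)
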