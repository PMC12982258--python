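"""End-to-end cohort analysis: group comparisons, covariate adjustment,
correlation battery and censoring-based sensitivity analyses.

The analysis plan mirrors a standard two-diagnosis (PD vs MSA) brainstem
volumetry study stratified by orthostatic hypotension:

1. primary comparisons — Mann-Whitney U on LC and SNc volumes, PD vs MSA;
2. subgroup comparisons — 4-level Kruskal-Wallis over PD(-)OH, PD(+)OH,
   MSA(-)OH, MSA(+)OH, with Dunn post hoc pairs (Bonferroni) run only when
   the omnibus is significant;
3. covariate-adjusted comparisons — Quade's nonparametric ANCOVA per
   covariate set (scanner protocol; age + disease duration + RBDSQ group),
   on the diagnosis factor and on the 4-level subgroup factor;
4. correlation battery — Spearman rho between LC volume and {supine MAP,
   supine HR, average orthostatic change in MAP, average change in HR} in
   each stratum (all subjects, PD, MSA, and the four subgroups), with
   Benjamini-Hochberg FDR across the whole battery;
5. sensitivity — for each censor tag (e.g. the cerebellar-MSA subject,
   alpha/beta-blocker users), the fragments are re-run on the censored
   cohort and significance flips at alpha on raw p are reported.

Empty or too-small strata produce warnings and skips, never silent omission
or a crash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .autonomic import (
    AutonomicLabel,
    OrthostaticPanel,
    label_subject,
    mean_arterial_pressure,
)
from .stats import (
    CorrelationResult,
    TestResult,
    adjust_pvalues,
    dunn_posthoc,
    kruskal_wallis,
    mann_whitney_u,
    quade_ancova,
    spearman,
)

__all__ = [
    "SubjectRecord",
    "PipelineConfig",
    "AnalysisReport",
    "SUBGROUPS",
    "subgroup_of",
    "ensure_labels",
    "stratify",
    "run_primary_comparisons",
    "run_subgroup_comparisons",
    "run_adjusted_comparisons",
    "run_correlation_battery",
    "run_sensitivity",
    "run_full_analysis",
]

SUBGROUPS = ("PD(-)OH", "PD(+)OH", "MSA(-)OH", "MSA(+)OH")

#: default covariate sets for the adjusted comparisons
DEFAULT_COVARIATE_SETS: tuple[tuple[str, ...], ...] = (
    ("scanner_protocol",),
    ("age", "disease_duration", "rbdsq_group"),
)


@dataclass
class SubjectRecord:
    """One subject: volumes, vitals panel, covariates and derived labels."""

    subject_id: str
    diagnosis: str  # "PD" | "MSA"
    lc_volume_mm3: float
    snc_volume_mm3: float
    panel: Optional[OrthostaticPanel]
    age: float
    disease_duration: float
    rbdsq_group: str = "low"  # "low" | "high"
    scanner_protocol: str = "A"  # "A" | "B"
    censor_flags: frozenset = frozenset()
    label: Optional[AutonomicLabel] = None
    true_subgroup: Optional[str] = None

    def __post_init__(self) -> None:
        if self.diagnosis not in ("PD", "MSA"):
            raise ValueError(f"diagnosis must be PD or MSA, got {self.diagnosis!r}")
        if self.lc_volume_mm3 < 0 or self.snc_volume_mm3 < 0:
            raise ValueError("volumes must be nonnegative")
        self.censor_flags = frozenset(self.censor_flags)


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-plan settings."""

    alpha: float = 0.05
    posthoc_only_if_omnibus: bool = True
    require_minute3: bool = False
    covariate_sets: tuple[tuple[str, ...], ...] = DEFAULT_COVARIATE_SETS
    censor_tags: tuple[str, ...] = ("msa_c", "alpha_beta_blocker")
    min_stratum_n: int = 3
    seed: Optional[int] = None

    def hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Structured result of one full pipeline run."""

    primary_comparisons: dict
    subgroup_comparisons: dict
    covariate_adjusted: dict
    correlations: list[CorrelationResult]
    sensitivity: dict
    subgroup_sizes: dict
    warnings: list[str]
    provenance: dict

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Machine-readable tables, one per fragment."""
        rows = []
        for target, tr in self.primary_comparisons.items():
            rows.append(_tr_row("primary PD vs MSA", target, tr))
        primary = pd.DataFrame(rows)

        rows = []
        for target, frag in self.subgroup_comparisons.items():
            if frag.get("omnibus") is not None:
                rows.append(_tr_row("subgroup omnibus", target, frag["omnibus"]))
            for tr in frag.get("posthoc") or []:
                pair = "{} vs {}".format(*tr.notes["pair"])
                rows.append(_tr_row(f"Dunn {pair}", target, tr))
        subgroup = pd.DataFrame(rows)

        rows = []
        for key, tr in self.covariate_adjusted.items():
            rows.append(_tr_row(key, "LC", tr))
        adjusted = pd.DataFrame(rows)

        rows = []
        for cr in self.correlations:
            rows.append(
                {
                    "stratum": cr.pair[0],
                    "variable": cr.pair[1],
                    "rho": cr.rho,
                    "p_raw": cr.p_raw,
                    "p_adjusted": cr.p_adjusted,
                    "n": cr.n,
                    "family": "correlation_battery",
                    "adjustment": "bh_fdr",
                }
            )
        correlations = pd.DataFrame(rows)

        rows = []
        for tag, frag in self.sensitivity.items():
            for key, flip in frag["flips"].items():
                rows.append(
                    {
                        "censor_tag": tag,
                        "comparison": key,
                        "p_baseline": flip["p_baseline"],
                        "p_censored": flip["p_censored"],
                        "flipped": flip["flipped"],
                    }
                )
        sensitivity = pd.DataFrame(rows)
        return {
            "primary": primary,
            "subgroup": subgroup,
            "adjusted": adjusted,
            "correlations": correlations,
            "sensitivity": sensitivity,
        }

    def save(self, outdir) -> None:
        """Write delimited-text tables, a formatted report, and a run log."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        frames = self.to_frames()
        for name, frame in frames.items():
            frame.to_csv(out / f"{name}.csv", index=False)
        lines = ["# Cohort analysis report", ""]
        lines.append(f"subgroup sizes: {self.subgroup_sizes}")
        lines.append(f"provenance: {self.provenance}")
        lines.append("")
        for name, frame in frames.items():
            lines.append(f"## {name}")
            lines.append(frame.to_string(index=False) if len(frame) else "(empty)")
            lines.append("")
        (out / "report.txt").write_text("\n".join(lines))
        (out / "run.log").write_text("\n".join(self.warnings) + "\n")


def _tr_row(comparison: str, target: str, tr: TestResult) -> dict:
    return {
        "comparison": comparison,
        "target": target,
        "method": tr.method,
        "statistic": tr.statistic,
        "p_raw": tr.p_raw,
        "p_adjusted": tr.p_adjusted,
        "group_sizes": "/".join(str(s) for s in tr.group_sizes),
        "family": comparison.split(" ")[0],
        "adjustment": "bonferroni" if tr.p_adjusted is not None else "none",
    }


# ---------------------------------------------------------------------------
# Cohort handling


def ensure_labels(
    cohort: Sequence[SubjectRecord], require_minute3: bool = False
) -> list[str]:
    """Compute autonomic labels in place where missing; return warnings.

    Subjects with no panel (or no standing data) cannot be labelled and are
    flagged; downstream stratification excludes them.
    """
    warnings = []
    for rec in cohort:
        if rec.label is not None:
            continue
        if rec.panel is None:
            warnings.append(f"{rec.subject_id}: no vitals panel; subject unlabelled")
            continue
        try:
            rec.label = label_subject(rec.panel, require_minute3=require_minute3)
        except ValueError as exc:
            warnings.append(f"{rec.subject_id}: {exc}; subject unlabelled")
    return warnings


def subgroup_of(rec: SubjectRecord) -> Optional[str]:
    if rec.label is None:
        return None
    sign = "+" if rec.label.oh_subgroup_positive else "-"
    return f"{rec.diagnosis}({sign})OH"


def stratify(
    cohort: Sequence[SubjectRecord],
) -> tuple[dict[str, list[SubjectRecord]], list[str]]:
    """Partition into the four diagnosis x OH subgroups.

    Returns ``(strata, warnings)``; empty subgroups are reported, not fatal.
    """
    strata: dict[str, list[SubjectRecord]] = {name: [] for name in SUBGROUPS}
    warnings = []
    for rec in cohort:
        name = subgroup_of(rec)
        if name is None:
            warnings.append(f"{rec.subject_id}: unlabelled; excluded from strata")
            continue
        strata[name].append(rec)
    for name, members in strata.items():
        if not members:
            warnings.append(f"subgroup {name} is empty; comparisons involving it skipped")
    return strata, warnings


def _volumes(records: Sequence[SubjectRecord], target: str) -> np.ndarray:
    attr = "lc_volume_mm3" if target == "LC" else "snc_volume_mm3"
    return np.asarray([getattr(r, attr) for r in records], dtype=float)


# ---------------------------------------------------------------------------
# Fragments


def run_primary_comparisons(cohort: Sequence[SubjectRecord]) -> dict:
    """Mann-Whitney U on LC and SNc volumes, PD vs MSA."""
    pd_recs = [r for r in cohort if r.diagnosis == "PD"]
    msa_recs = [r for r in cohort if r.diagnosis == "MSA"]
    out: dict = {"warnings": []}
    if len(pd_recs) < 2 or len(msa_recs) < 2:
        out["warnings"].append(
            f"primary comparison skipped: PD n={len(pd_recs)}, MSA n={len(msa_recs)}"
        )
        return out
    for target in ("LC", "SNc"):
        out[target] = mann_whitney_u(_volumes(pd_recs, target), _volumes(msa_recs, target))
    return out


def run_subgroup_comparisons(
    cohort: Sequence[SubjectRecord], config: PipelineConfig = PipelineConfig()
) -> dict:
    """4-level Kruskal-Wallis per target; Dunn pairs gated on the omnibus."""
    strata, warnings = stratify(cohort)
    present = [name for name in SUBGROUPS if strata[name]]
    out: dict = {"warnings": warnings}
    if len(present) < 2:
        out["warnings"].append("fewer than 2 non-empty subgroups; omnibus skipped")
        return out
    for target in ("LC", "SNc"):
        groups = [_volumes(strata[name], target) for name in present]
        omnibus = kruskal_wallis(groups)
        frag = {"omnibus": omnibus, "posthoc": None, "levels": present}
        if (not config.posthoc_only_if_omnibus) or omnibus.p_raw < config.alpha:
            frag["posthoc"] = dunn_posthoc(groups, fwe="bonferroni", labels=present)
        out[target] = frag
    return out


def _covariate_matrix(
    records: Sequence[SubjectRecord], names: Sequence[str]
) -> tuple[list[np.ndarray], list[str]]:
    """Numeric covariate columns; categoricals enter as integer codes."""
    codes = {"scanner_protocol": {"A": 0, "B": 1}, "rbdsq_group": {"low": 0, "high": 1}}
    cols, warnings = [], []
    for name in names:
        if name in codes:
            col = np.asarray([codes[name][getattr(r, name)] for r in records], float)
        else:
            col = np.asarray([getattr(r, name) for r in records], float)
        if np.unique(col).size < 2:
            warnings.append(f"covariate {name} is constant; dropped")
            continue
        cols.append(col)
    return cols, warnings


def run_adjusted_comparisons(
    cohort: Sequence[SubjectRecord],
    covariate_sets: Sequence[Sequence[str]] = DEFAULT_COVARIATE_SETS,
) -> dict:
    """Quade ANCOVA on LC volume: diagnosis factor and 4-level subgroup factor."""
    labelled = [r for r in cohort if r.label is not None]
    out: dict = {"warnings": []}
    if len(labelled) < 8:
        out["warnings"].append("too few labelled subjects for adjusted comparisons")
        return out
    response = _volumes(labelled, "LC")
    diagnosis = [r.diagnosis for r in labelled]
    subgroups = [subgroup_of(r) for r in labelled]
    for names in covariate_sets:
        cols, warns = _covariate_matrix(labelled, names)
        out["warnings"].extend(warns)
        key_base = "+".join(names) if names else "unadjusted"
        for factor_name, factor in (("diagnosis", diagnosis), ("subgroup", subgroups)):
            if len(set(factor)) < 2:
                out["warnings"].append(
                    f"factor {factor_name} has <2 levels; Quade skipped"
                )
                continue
            out[f"quade[{key_base}] on {factor_name}"] = quade_ancova(
                response, factor, cols
            )
    return out


BATTERY_VARIABLES = ("supine_map", "supine_hr", "avg_delta_map", "avg_delta_hr")


def _battery_value(rec: SubjectRecord, variable: str) -> float:
    assert rec.panel is not None and rec.label is not None
    if variable == "supine_map":
        return mean_arterial_pressure(rec.panel.supine.sbp, rec.panel.supine.dbp)
    if variable == "supine_hr":
        return rec.panel.supine.hr
    if variable == "avg_delta_map":
        return rec.label.avg_delta_map
    if variable == "avg_delta_hr":
        return rec.label.avg_delta_hr
    raise ValueError(f"unknown battery variable {variable!r}")


def run_correlation_battery(
    cohort: Sequence[SubjectRecord], min_n: int = 3
) -> tuple[list[CorrelationResult], list[str]]:
    """Spearman rho of LC volume vs orthostatic vitals per stratum.

    One BH-FDR family across every stratum x variable pair computed in the
    run.  Strata below ``min_n`` are skipped with a warning.
    """
    strata, warnings = stratify(cohort)
    labelled = [r for r in cohort if r.label is not None and r.panel is not None]
    named_strata: list[tuple[str, list[SubjectRecord]]] = [
        ("all", labelled),
        ("PD", [r for r in labelled if r.diagnosis == "PD"]),
        ("MSA", [r for r in labelled if r.diagnosis == "MSA"]),
    ] + [(name, strata[name]) for name in SUBGROUPS]
    results: list[CorrelationResult] = []
    for name, members in named_strata:
        if len(members) < min_n:
            warnings.append(
                f"stratum {name} has n={len(members)} < {min_n}; correlations skipped"
            )
            continue
        lc = _volumes(members, "LC")
        for variable in BATTERY_VARIABLES:
            vals = np.asarray([_battery_value(r, variable) for r in members])
            results.append(spearman(lc, vals, pair=(name, variable)))
    defined = [r for r in results if not np.isnan(r.p_raw)]
    if defined:
        adj = adjust_pvalues([r.p_raw for r in defined], "bh_fdr")
        for r, a in zip(defined, adj):
            r.p_adjusted = a
    return results, warnings


# ---------------------------------------------------------------------------
# Sensitivity


def _significance_map(
    primary: dict, subgroup: dict, correlations: list[CorrelationResult]
) -> dict[str, float]:
    """Flatten raw p-values of every surfaced comparison under stable keys."""
    out: dict[str, float] = {}
    for target in ("LC", "SNc"):
        if target in primary:
            out[f"primary/{target}"] = primary[target].p_raw
        frag = subgroup.get(target)
        if frag and frag.get("omnibus") is not None:
            out[f"omnibus/{target}"] = frag["omnibus"].p_raw
            for tr in frag.get("posthoc") or []:
                pair = "{}|{}".format(*tr.notes["pair"])
                out[f"dunn/{target}/{pair}"] = tr.p_raw
    for cr in correlations:
        out[f"rho/{cr.pair[0]}/{cr.pair[1]}"] = cr.p_raw
    return out


def run_sensitivity(
    cohort: Sequence[SubjectRecord],
    censor_tags: Sequence[str],
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Re-run the comparison fragments with tagged subjects censored.

    A flip is a comparison whose raw p crosses ``config.alpha`` between the
    baseline and censored runs (in either direction), or one that exists in
    only one of the runs (e.g. a stratum emptied by censoring).
    """
    base_primary = run_primary_comparisons(cohort)
    base_subgroup = run_subgroup_comparisons(cohort, config)
    base_corr, _ = run_correlation_battery(cohort, config.min_stratum_n)
    baseline = _significance_map(base_primary, base_subgroup, base_corr)
    out: dict = {}
    for tag in censor_tags:
        censored = [r for r in cohort if tag not in r.censor_flags]
        n_removed = len(cohort) - len(censored)
        primary = run_primary_comparisons(censored)
        subgroup = run_subgroup_comparisons(censored, config)
        corr, warns = run_correlation_battery(censored, config.min_stratum_n)
        cens = _significance_map(primary, subgroup, corr)
        flips = {}
        for key in sorted(set(baseline) | set(cens)):
            p0, p1 = baseline.get(key), cens.get(key)
            if p0 is None or p1 is None or np.isnan(p0) or np.isnan(p1):
                flipped = p0 is not p1  # comparison appeared or disappeared
            else:
                flipped = (p0 < config.alpha) != (p1 < config.alpha)
            flips[key] = {"p_baseline": p0, "p_censored": p1, "flipped": bool(flipped)}
        out[tag] = {
            "n_removed": n_removed,
            "flips": flips,
            "n_flipped": sum(f["flipped"] for f in flips.values()),
            "warnings": warns,
        }
    return out


# ---------------------------------------------------------------------------
# Orchestration


def run_full_analysis(
    cohort: Sequence[SubjectRecord],
    config: PipelineConfig = PipelineConfig(),
) -> AnalysisReport:
    """Execute the full analysis plan and assemble the report.

    Deterministic for a fixed cohort and config: the report contains no
    timestamps or other run-varying fields unless the caller adds them to
    provenance afterwards.
    """
    warnings = ensure_labels(cohort, require_minute3=config.require_minute3)
    strata, strat_warnings = stratify(cohort)
    warnings.extend(strat_warnings)

    primary = run_primary_comparisons(cohort)
    warnings.extend(primary.pop("warnings", []))
    subgroup = run_subgroup_comparisons(cohort, config)
    warnings.extend(subgroup.pop("warnings", []))
    adjusted = run_adjusted_comparisons(cohort, config.covariate_sets)
    warnings.extend(adjusted.pop("warnings", []))
    correlations, corr_warnings = run_correlation_battery(cohort, config.min_stratum_n)
    warnings.extend(corr_warnings)
    sensitivity = run_sensitivity(cohort, config.censor_tags, config)

    return AnalysisReport(
        primary_comparisons=primary,
        subgroup_comparisons=subgroup,
        covariate_adjusted=adjusted,
        correlations=correlations,
        sensitivity=sensitivity,
        subgroup_sizes={name: len(strata[name]) for name in SUBGROUPS},
        warnings=warnings,
        provenance={"seed": config.seed, "config_hash": config.hash(), "n": len(cohort)},
    )
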