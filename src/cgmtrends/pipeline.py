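"""End-to-end analysis: study -> concordance report.

For each system and each reference trace (the sensor's own tissue-glucose
trace, and optionally the participant's blood-glucose trace) the pipeline
pairs every diary arrow with the category of the realized 30-min rate and
tabulates: the overall summary, per-visit summaries, event-window strata
with the inside fraction, parallel-sensor agreement (TG diaries only, once
per system), the full recorded x calculated contingency table, and exclusion
counts by reason.  The report echoes the conventions it was computed under
(boundary rule, horizon, gap caps, window bounds) so results are
reproducible from the report alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .concordance import (
    AgreementSummary,
    ConcordanceSummary,
    build_concordance,
    contingency,
    parallel_sensor_agreement,
    stratify_by_visit,
    summarize,
    BG_MAX_GAP_MIN,
)
from .events import DEFAULT_POST_MIN, DEFAULT_PRE_MIN, stratified_summary
from .profiles import PROFILES
from .simulate import Study
from .traces import default_max_gap

__all__ = ["AnalysisOptions", "StratumReport", "AnalysisReport", "run_pipeline"]


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable analysis conventions."""

    horizon_min: float = 30.0
    max_gap_min: float | None = None      # None -> 2.5x device cadence
    bg_max_gap_min: float = BG_MAX_GAP_MIN
    window_pre_min: float = DEFAULT_PRE_MIN
    window_post_min: float = DEFAULT_POST_MIN
    references: tuple[str, ...] = ("TG", "BG")

    def to_dict(self) -> dict:
        return {
            "horizon_min": self.horizon_min,
            "max_gap_min": self.max_gap_min,
            "bg_max_gap_min": self.bg_max_gap_min,
            "window_pre_min": self.window_pre_min,
            "window_post_min": self.window_post_min,
            "references": list(self.references),
            "boundary_convention": "threshold rates assigned to the less-extreme category",
            "window_boundary_convention": "strict inequalities (boundaries outside)",
        }


@dataclass
class StratumReport:
    """All statistics for one system under one reference trace."""

    system: str
    reference: str
    overall: ConcordanceSummary
    by_visit: dict[int, ConcordanceSummary]
    inside: ConcordanceSummary
    outside: ConcordanceSummary
    pct_inside: float | None
    contingency: pd.DataFrame
    exclusions: Counter
    agreement: AgreementSummary | None = None  # TG reference only


@dataclass
class AnalysisReport:
    strata: dict[tuple[str, str], StratumReport]  # (system, reference) -> report
    options: AnalysisOptions
    manifest: dict = field(default_factory=dict)

    def get(self, system: str, reference: str = "TG") -> StratumReport:
        return self.strata[(system, reference)]

    def to_dict(self) -> dict:
        out: dict = {"options": self.options.to_dict(), "systems": {}}
        for (system, reference), rep in sorted(self.strata.items()):
            out["systems"].setdefault(system, {})[reference] = _stratum_dict(rep)
        return out

    def write(self, out_dir: str | Path) -> Path:
        """Write report.yaml plus one contingency CSV per system/reference."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (system, reference), rep in self.strata.items():
            rep.contingency.to_csv(out / f"contingency_{system}_{reference}.csv")
        path = out / "report.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


def _summary_dict(s: ConcordanceSummary) -> dict:
    return {
        "n": s.n,
        "counts": {"match": s.n_match, "off1": s.n_off1, "off2plus": s.n_off2plus},
        "pct": {"match": s.pct_match, "off1": s.pct_off1, "off2plus": s.pct_off2plus},
        "participant_mean_match": s.participant_mean_match,
        "participant_sd_match": s.participant_sd_match,
    }


def _stratum_dict(rep: StratumReport) -> dict:
    d = {
        "overall": _summary_dict(rep.overall),
        "by_visit": {v: _summary_dict(s) for v, s in rep.by_visit.items()},
        "event_windows": {
            "inside": _summary_dict(rep.inside),
            "outside": _summary_dict(rep.outside),
            "pct_inside": rep.pct_inside,
        },
        "exclusions": dict(rep.exclusions),
    }
    if rep.agreement is not None:
        a = rep.agreement
        d["parallel_sensor_agreement"] = {
            "n_pairs": a.n_pairs,
            "n_unpaired": a.n_unpaired,
            "pct": {"identical": a.pct_identical, "off1": a.pct_off1, "off2plus": a.pct_off2plus},
        }
    return d


def run_pipeline(study: Study, options: AnalysisOptions | None = None) -> AnalysisReport:
    """Run every analysis stage for both systems and all requested
    reference traces; deterministic for fixed inputs."""
    options = options or AnalysisOptions()
    strata: dict[tuple[str, str], StratumReport] = {}
    for system, profile in PROFILES.items():
        diary = study.diary_for(system)
        for reference in options.references:
            traces = study.traces if reference == "TG" else study.bg
            max_gap = (
                options.max_gap_min
                if options.max_gap_min is not None
                else default_max_gap(profile.storage_interval)
            )
            if reference == "BG":
                max_gap = options.bg_max_gap_min
            records, exclusions = build_concordance(
                diary,
                traces,
                study.events,
                profile,
                reference=reference,
                horizon=options.horizon_min,
                max_gap=max_gap,
                window_pre=options.window_pre_min,
                window_post=options.window_post_min,
            )
            inside, outside, pct_inside = stratified_summary(records)
            strata[(system, reference)] = StratumReport(
                system=system,
                reference=reference,
                overall=summarize(records),
                by_visit=stratify_by_visit(records),
                inside=inside,
                outside=outside,
                pct_inside=pct_inside,
                contingency=contingency(records, profile),
                exclusions=Counter(e.reason for e in exclusions),
                agreement=parallel_sensor_agreement(diary, system)
                if reference == "TG"
                else None,
            )
    return AnalysisReport(strata=strata, options=options, manifest=dict(study.manifest))


def _fmt(x: float | None) -> str:
    return "-" if x is None else f"{x:.1f}"


def render_report(report: AnalysisReport) -> str:
    """Human-readable table rendering of a report."""
    lines: list[str] = []
    for (system, reference), rep in sorted(report.strata.items()):
        lines.append(f"=== {system} vs {reference} reference ===")
        o = rep.overall
        lines.append(
            f"overall        n={o.n:5d}  match {_fmt(o.pct_match)}%  "
            f"off-by-1 {_fmt(o.pct_off1)}%  off>=2 {_fmt(o.pct_off2plus)}%"
        )
        for v, s in rep.by_visit.items():
            lines.append(
                f"visit {v}        n={s.n:5d}  match {_fmt(s.pct_match)}%  "
                f"off-by-1 {_fmt(s.pct_off1)}%  off>=2 {_fmt(s.pct_off2plus)}%"
            )
        lines.append(
            f"event windows  inside n={rep.inside.n} match {_fmt(rep.inside.pct_match)}%  "
            f"outside n={rep.outside.n} match {_fmt(rep.outside.pct_match)}%  "
            f"inside fraction {_fmt(rep.pct_inside)}%"
        )
        if rep.agreement is not None:
            a = rep.agreement
            lines.append(
                f"parallel sensors  pairs={a.n_pairs} identical {_fmt(a.pct_identical)}%  "
                f"off-by-1 {_fmt(a.pct_off1)}%  off>=2 {_fmt(a.pct_off2plus)}%"
            )
        if rep.exclusions:
            reasons = ", ".join(f"{k}={v}" for k, v in sorted(rep.exclusions.items()))
            lines.append(f"exclusions     {reasons}")
        lines.append("")
    return "\n".join(lines)
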