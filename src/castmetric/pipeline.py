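"""End-to-end study orchestration.

A study emulates the full cast-accuracy experiment: simulate (or ingest)
one reference scan plus groups of test scans, run every configured trueness
pairing and precision group through the align -> trim -> measure ->
summarize chain, compute the group-comparison statistics, and write
machine-readable tables plus a provenance record.  Runs are deterministic
given (config, seed): re-running writes byte-identical reports.

The default configuration mirrors the study design this package targets:
four trueness pairings ([REF vs GYPSUM], [REF vs DLP], [REF vs IOS] with
the reference cast as reference object, and [IOS vs DLP] paired by
replicate with the intraoral scan as reference object) and three precision
groups of ten scans each, i.e. 45 pairwise superimpositions per group.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .comparison import TrimPlane
from .errors import ParameterError
from .mesh import TriangleMesh
from .mesh_io import read_stl
from .statistics import (
    ComparisonConfig,
    GroupResult,
    StatTestResult,
    compare_groups,
    paired_trueness_analysis,
    precision_analysis,
    trueness_analysis,
)
from .synthetic_data import (
    DEFAULT_GROUP_PLAN,
    DeformationRecipe,
    StudySet,
    SyntheticArchSpec,
    generate_study_set,
)

REFERENCE_LABEL = "REF"


@dataclass(frozen=True)
class TruenessPairing:
    """One trueness comparison: a test group measured against a reference
    object (the dedicated reference scan, or another group when paired)."""

    label: str
    reference: str  # REFERENCE_LABEL or a group name
    test_group: str
    paired: bool = False


@dataclass(frozen=True)
class StatPlanEntry:
    """One planned two-sample comparison between result families."""

    label: str
    kind_a: str  # "trueness" | "precision"
    family_a: str
    kind_b: str
    family_b: str
    metric: str = "abs_mean_um"
    paired: bool = False
    correction_factor: float = 1.0


def default_trueness_pairings() -> list[TruenessPairing]:
    return [
        TruenessPairing("REF_vs_GYPSUM", REFERENCE_LABEL, "GYPSUM"),
        TruenessPairing("REF_vs_DLP", REFERENCE_LABEL, "DLP"),
        TruenessPairing("REF_vs_IOS", REFERENCE_LABEL, "IOS"),
        TruenessPairing("IOS_vs_DLP", "IOS", "DLP", paired=True),
    ]


def default_stat_plan() -> list[StatPlanEntry]:
    """The published analysis plan: workflow comparison plus the digital
    family (Bonferroni factor 3), for both summary metrics, and the
    precision contrasts."""
    plan: list[StatPlanEntry] = []
    for metric in ("abs_mean_um", "rmse_um"):
        m = metric.split("_um")[0]
        plan.append(
            StatPlanEntry(
                f"trueness_{m}_GYPSUM_vs_DLP",
                "trueness", "REF_vs_GYPSUM", "trueness", "REF_vs_DLP",
                metric=metric,
            )
        )
        digital = [
            ("REF_vs_IOS", "IOS_vs_DLP"),
            ("REF_vs_IOS", "REF_vs_DLP"),
            ("IOS_vs_DLP", "REF_vs_DLP"),
        ]
        for a, b in digital:
            plan.append(
                StatPlanEntry(
                    f"trueness_{m}_{a}_vs_{b}",
                    "trueness", a, "trueness", b,
                    metric=metric, paired=True, correction_factor=3.0,
                )
            )
        plan.append(
            StatPlanEntry(
                f"precision_{m}_GYPSUM_vs_DLP",
                "precision", "GYPSUM", "precision", "DLP",
                metric=metric,
            )
        )
        plan.append(
            StatPlanEntry(
                f"precision_{m}_DLP_vs_IOS",
                "precision", "DLP", "precision", "IOS",
                metric=metric, paired=True,
            )
        )
    return plan


@dataclass
class StudyConfig:
    """Everything needed to reproduce one study run."""

    mode: str = "simulate"  # "simulate" | "ingest"
    spec: SyntheticArchSpec = field(default_factory=SyntheticArchSpec)
    group_plan: dict[str, DeformationRecipe] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PLAN)
    )
    n_per_group: int = 10
    # ingest mode: paths instead of simulation
    reference_path: str | None = None
    group_paths: dict[str, list[str]] = field(default_factory=dict)
    # analysis knobs
    lower_q: float = 0.01
    upper_q: float = 0.99
    tolerance_mm: float = 2.0
    trim_height: float | None = None  # None: half the base height (simulate mode)
    icp_sample_size: int = 25_000
    icp_max_iterations: int = 100
    icp_tolerance: float = 1e-6
    trueness_pairings: list[TruenessPairing] = field(
        default_factory=default_trueness_pairings
    )
    precision_groups: list[str] = field(
        default_factory=lambda: ["GYPSUM", "DLP", "IOS"]
    )
    stat_plan: list[StatPlanEntry] = field(default_factory=default_stat_plan)
    alpha: float = 0.05
    seed: int = 0

    def comparison_config(self) -> ComparisonConfig:
        if self.trim_height is not None:
            plane = TrimPlane.horizontal(self.trim_height)
        elif self.mode == "simulate":
            plane = TrimPlane.horizontal(self.spec.base_height / 2.0)
        else:
            plane = None
        return ComparisonConfig(
            lower_q=self.lower_q,
            upper_q=self.upper_q,
            tolerance_mm=self.tolerance_mm,
            trim_plane=plane,
            icp_sample_size=self.icp_sample_size,
            icp_max_iterations=self.icp_max_iterations,
            icp_tolerance=self.icp_tolerance,
            icp_seed=self.seed,
        )

    def validate(self) -> None:
        groups = (
            set(self.group_plan)
            if self.mode == "simulate"
            else set(self.group_paths)
        )
        for p in self.trueness_pairings:
            if p.test_group not in groups:
                raise ParameterError(f"pairing {p.label}: unknown group {p.test_group}")
            if p.reference != REFERENCE_LABEL and p.reference not in groups:
                raise ParameterError(
                    f"pairing {p.label}: unknown reference {p.reference}"
                )
        for g in self.precision_groups:
            if g not in groups:
                raise ParameterError(f"precision group {g} unknown")


def demo_config(seed: int = 0) -> StudyConfig:
    """The packaged synthetic demonstration study.

    Mesh density and ICP sampling are reduced relative to clinical-scan
    resolution so the full 75-superimposition study completes on a laptop in
    minutes; deformation magnitudes are the package defaults.
    """
    return StudyConfig(
        spec=SyntheticArchSpec(target_vertices=30_000, seed=seed),
        icp_sample_size=5_000,
        icp_tolerance=1e-5,
        seed=seed,
    )


@dataclass
class StudyReport:
    """All results of one run, with table views."""

    config: StudyConfig
    trueness: dict[str, GroupResult]
    precision: dict[str, GroupResult]
    stats: dict[str, StatTestResult]

    def _per_comparison_frame(self, results: dict[str, GroupResult]) -> pd.DataFrame:
        rows = []
        for label, gr in results.items():
            for cmp_label, s in zip(gr.comparison_labels, gr.summaries):
                rows.append(
                    {
                        "pairing": label,
                        "comparison": cmp_label,
                        "abs_mean_um": s.abs_mean_um,
                        "rmse_um": s.rmse_um,
                        "median_um": s.median_um,
                        "sd_um": s.sd_um,
                        "min_um": s.min_um,
                        "max_um": s.max_um,
                        "retained_count": s.retained_count,
                    }
                )
        return pd.DataFrame(rows)

    def _summary_frame(self, results: dict[str, GroupResult]) -> pd.DataFrame:
        rows = []
        for label, gr in results.items():
            row: dict[str, object] = {"pairing": label, "n": len(gr.summaries)}
            for metric, prefix in (("abs_mean_um", "abs_mean"), ("rmse_um", "rmse")):
                ag = gr.aggregate(metric)
                for key in ("min", "max", "mean", "sd", "median"):
                    row[f"{prefix}_{key}_um"] = ag[key]
            rows.append(row)
        return pd.DataFrame(rows)

    def trueness_frame(self) -> pd.DataFrame:
        return self._per_comparison_frame(self.trueness)

    def trueness_summary_frame(self) -> pd.DataFrame:
        return self._summary_frame(self.trueness)

    def precision_frame(self) -> pd.DataFrame:
        return self._per_comparison_frame(self.precision)

    def precision_summary_frame(self) -> pd.DataFrame:
        return self._summary_frame(self.precision)

    def alignments_frame(self) -> pd.DataFrame:
        """Per-superimposition log: ICP iterations, final RMS, discarded points."""
        rows = []
        for kind, results in (("trueness", self.trueness), ("precision", self.precision)):
            for label, gr in results.items():
                for cmp_label, icp, discarded in zip(
                    gr.comparison_labels, gr.icp_results, gr.discarded_counts
                ):
                    rows.append(
                        {
                            "kind": kind,
                            "pairing": label,
                            "comparison": cmp_label,
                            "icp_iterations": icp.iterations,
                            "icp_rms_um": icp.rms * 1000.0,
                            "converged": icp.converged,
                            "discarded_points": discarded,
                        }
                    )
        return pd.DataFrame(rows)

    def stats_frame(self) -> pd.DataFrame:
        rows = []
        for label, r in self.stats.items():
            rows.append(
                {
                    "comparison": label,
                    "test": r.test_name,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "p_corrected": r.p_corrected,
                    "correction_factor": r.correction_factor,
                    "significant": r.significant,
                }
            )
        return pd.DataFrame(rows)


def _load_ingest(config: StudyConfig) -> tuple[TriangleMesh, dict[str, list[TriangleMesh]]]:
    if config.reference_path is None:
        raise ParameterError("ingest mode requires reference_path")
    reference = read_stl(config.reference_path)
    groups = {
        name: [read_stl(p) for p in paths]
        for name, paths in config.group_paths.items()
    }
    return reference, groups


def run_study(
    config: StudyConfig,
    out_dir: str | Path | None = None,
    study_set: StudySet | None = None,
) -> StudyReport:
    """Execute every configured trueness pairing and precision group.

    ``study_set`` short-circuits simulation (reuse between runs); otherwise
    simulate-mode generates it from the config's spec, plan and seed.
    Writes CSV tables, a JSON mirror and a provenance record when
    ``out_dir`` is given.
    """
    config.validate()
    cfg = config.comparison_config()
    if study_set is not None:
        reference, groups = study_set.reference, study_set.groups
    elif config.mode == "simulate":
        study_set = generate_study_set(
            config.spec, config.group_plan, config.n_per_group, config.seed
        )
        reference, groups = study_set.reference, study_set.groups
    elif config.mode == "ingest":
        reference, groups = _load_ingest(config)
    else:
        raise ParameterError(f"unknown mode {config.mode!r}")

    trueness: dict[str, GroupResult] = {}
    for pairing in config.trueness_pairings:
        tests = groups[pairing.test_group]
        try:
            if pairing.reference == REFERENCE_LABEL:
                trueness[pairing.label] = trueness_analysis(
                    reference, tests, cfg, label=pairing.label
                )
            elif pairing.paired:
                trueness[pairing.label] = paired_trueness_analysis(
                    groups[pairing.reference], tests, cfg, label=pairing.label
                )
            else:
                raise ParameterError(
                    f"pairing {pairing.label}: group-vs-group must be paired"
                )
        except Exception as exc:
            raise type(exc)(f"trueness pairing {pairing.label}: {exc}") from exc

    precision: dict[str, GroupResult] = {}
    for name in config.precision_groups:
        try:
            precision[name] = precision_analysis(groups[name], cfg, label=name)
        except Exception as exc:
            raise type(exc)(f"precision group {name}: {exc}") from exc

    stats: dict[str, StatTestResult] = {}
    pools = {"trueness": trueness, "precision": precision}
    for entry in config.stat_plan:
        fam_a = pools[entry.kind_a].get(entry.family_a)
        fam_b = pools[entry.kind_b].get(entry.family_b)
        if fam_a is None or fam_b is None:
            continue  # family not part of this run
        stats[entry.label] = compare_groups(
            fam_a.metric(entry.metric),
            fam_b.metric(entry.metric),
            paired=entry.paired,
            alpha=config.alpha,
            correction_factor=entry.correction_factor,
        )

    report = StudyReport(
        config=config, trueness=trueness, precision=precision, stats=stats
    )
    if out_dir is not None:
        write_report(report, Path(out_dir))
    return report


def _config_dict(config: StudyConfig) -> dict:
    d = asdict(config)
    return d


def write_report(report: StudyReport, out_dir: Path) -> None:
    """CSV tables, JSON mirror and provenance; byte-stable across re-runs."""
    out_dir.mkdir(parents=True, exist_ok=True)
    report.trueness_frame().to_csv(out_dir / "trueness.csv", index=False)
    report.trueness_summary_frame().to_csv(
        out_dir / "trueness_summary.csv", index=False
    )
    report.precision_frame().to_csv(out_dir / "precision.csv", index=False)
    report.precision_summary_frame().to_csv(
        out_dir / "precision_summary.csv", index=False
    )
    report.stats_frame().to_csv(out_dir / "stats.csv", index=False)
    report.alignments_frame().to_csv(out_dir / "alignments.csv", index=False)
    mirror = {
        "trueness": report.trueness_summary_frame().to_dict(orient="records"),
        "precision": report.precision_summary_frame().to_dict(orient="records"),
        "stats": report.stats_frame().to_dict(orient="records"),
    }
    (out_dir / "report.json").write_text(json.dumps(mirror, indent=2, sort_keys=True))
    cfg_json = json.dumps(_config_dict(report.config), sort_keys=True, default=str)
    provenance = {
        "castmetric_version": __version__,
        "seed": report.config.seed,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True)
    )
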