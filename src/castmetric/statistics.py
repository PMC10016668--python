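"""Quantile-trimmed deviation summaries and group-comparison statistics.

Summary statistics follow surface-metrology convention: the signed
deviations of one superimposition are first quantile-trimmed (default 99/1:
the highest and lowest 1% of the signed distribution are excluded), then
the *absolute* mean deviation, RMSE, median, SD, minimum and maximum of the
absolute deviations are reported in micrometres.

RMSE here is sqrt(mean(d_i^2)) of the point-to-surface distances d_i — the
dispersion of the test surface around the reference — so RMSE >= absolute
mean always (power-mean inequality).

Trueness compares each test scan against a designated reference object;
precision compares the scans of one group pairwise (all n(n-1)/2 unordered
pairs, the lower-index scan acting as reference object).

Group comparison applies a Shapiro-Wilk normality gate (alpha 0.05) to both
samples: if both pass, a t-test (paired or independent), otherwise
Mann-Whitney U (independent) or Wilcoxon signed-rank (paired); the p-value
is multiplied by an explicit Bonferroni correction factor and capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .comparison import (
    DEFAULT_TOLERANCE_MM,
    DeviationField,
    TrimPlane,
    measure_deviation,
)
from .errors import EmptyResultError, ParameterError
from .mesh import TriangleMesh
from .registration import IcpResult, SpatialIndex, icp_align

MM_TO_UM = 1000.0

logger = logging.getLogger(__name__)


def quantile_trim(
    values: Sequence[float] | np.ndarray,
    lower_q: float = 0.01,
    upper_q: float = 0.99,
    on_absolute: bool = False,
) -> np.ndarray:
    """Drop the lowest ``lower_q`` and highest ``1 - upper_q`` fraction of values.

    Rank-based: with n values, the ``floor(lower_q * n)`` smallest and the
    ``floor((1 - upper_q) * n)`` largest are removed (ties broken stably by
    position), so ``lower_q = 0, upper_q = 1`` is the identity.  Trimming
    operates on the signed values by default; ``on_absolute=True`` ranks by
    magnitude instead (then only the top fraction matters).
    """
    v = np.asarray(values, float).ravel()
    if len(v) == 0:
        raise ParameterError("values must be non-empty")
    if not (0 <= lower_q < upper_q <= 1):
        raise ParameterError("need 0 <= lower_q < upper_q <= 1")
    n = len(v)
    # epsilon guards the floor against float artifacts like (1-0.8)*5 = 0.999..
    n_lo = int(np.floor(lower_q * n + 1e-9))
    n_hi = int(np.floor((1.0 - upper_q) * n + 1e-9))
    if n_lo + n_hi >= n:
        raise EmptyResultError("quantile trimming removed every value")
    order = np.argsort(np.abs(v) if on_absolute else v, kind="stable")
    drop = np.zeros(n, bool)
    if n_lo:
        drop[order[:n_lo]] = True
    if n_hi:
        drop[order[n - n_hi :]] = True
    return v[~drop]


@dataclass(frozen=True)
class DeviationSummary:
    """Quantile-trimmed absolute deviation statistics of one superimposition.

    All distances in micrometres.
    """

    abs_mean_um: float
    rmse_um: float
    median_um: float
    sd_um: float
    min_um: float
    max_um: float
    lower_q: float
    upper_q: float
    retained_count: int

    def __post_init__(self) -> None:
        if not (
            -1e-9 <= self.min_um <= self.median_um + 1e-9
            and self.median_um <= self.max_um + 1e-9
        ):
            raise ParameterError("absolute statistics must satisfy min <= median <= max")
        if self.rmse_um < self.abs_mean_um - 1e-9:
            raise ParameterError("RMSE cannot be below the absolute mean")


def summarize_values(
    signed_mm: np.ndarray,
    lower_q: float = 0.01,
    upper_q: float = 0.99,
    trim_on_absolute: bool = False,
) -> DeviationSummary:
    """Trim signed distances, then compute absolute statistics in μm."""
    trimmed = quantile_trim(signed_mm, lower_q, upper_q, on_absolute=trim_on_absolute)
    a = np.abs(trimmed) * MM_TO_UM
    return DeviationSummary(
        abs_mean_um=float(a.mean()),
        rmse_um=float(np.sqrt(np.mean(a**2))),
        median_um=float(np.median(a)),
        sd_um=float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        min_um=float(a.min()),
        max_um=float(a.max()),
        lower_q=lower_q,
        upper_q=upper_q,
        retained_count=len(a),
    )


def summarize(
    field: DeviationField,
    lower_q: float = 0.01,
    upper_q: float = 0.99,
    trim_on_absolute: bool = False,
) -> DeviationSummary:
    """Quantile-trimmed summary of one deviation field."""
    if len(field) == 0:
        raise EmptyResultError("deviation field is empty")
    return summarize_values(field.distances, lower_q, upper_q, trim_on_absolute)


# ---------------------------------------------------------------------------
# experimental designs


@dataclass
class ComparisonConfig:
    """Shared knobs of one align -> trim -> measure -> summarize chain."""

    lower_q: float = 0.01
    upper_q: float = 0.99
    tolerance_mm: float = DEFAULT_TOLERANCE_MM
    trim_plane: TrimPlane | None = None
    icp_sample_size: int = 25_000
    icp_max_iterations: int = 100
    icp_tolerance: float = 1e-6
    icp_seed: int = 0
    trim_on_absolute: bool = False


@dataclass
class GroupResult:
    """Per-comparison summaries of one pairing or group, plus aggregates."""

    label: str
    summaries: list[DeviationSummary]
    icp_results: list[IcpResult] = field(default_factory=list)
    comparison_labels: list[str] = field(default_factory=list)
    discarded_counts: list[int] = field(default_factory=list)

    def metric(self, name: str) -> np.ndarray:
        """Per-comparison values of ``abs_mean_um`` or ``rmse_um`` (μm)."""
        return np.array([getattr(s, name) for s in self.summaries])

    def aggregate(self, name: str = "abs_mean_um") -> dict[str, float]:
        """Minimum / maximum / mean ± SD / median over per-comparison values."""
        v = self.metric(name)
        return {
            "min": float(v.min()),
            "max": float(v.max()),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            "median": float(np.median(v)),
            "n": len(v),
        }


def compare_pair(
    test: TriangleMesh,
    reference: TriangleMesh,
    config: ComparisonConfig,
    reference_index: SpatialIndex | None = None,
    reference_id: str = "reference",
    test_id: str = "test",
) -> tuple[DeviationField, IcpResult]:
    """One align -> trim -> measure chain; the reference object is fixed."""
    if reference_index is None:
        reference_index = SpatialIndex(reference)
    icp = icp_align(
        test,
        reference,
        max_iterations=config.icp_max_iterations,
        tolerance=config.icp_tolerance,
        cutoff_mm=config.tolerance_mm,
        sample_size=config.icp_sample_size,
        seed=config.icp_seed,
        index=reference_index,
    )
    fld = measure_deviation(
        test,
        reference,
        transform=icp.transform,
        plane=config.trim_plane,
        tolerance_mm=config.tolerance_mm,
        reference_id=reference_id,
        test_id=test_id,
        reference_index=reference_index if config.trim_plane is None else None,
    )
    logger.info(
        "%s vs %s: %d ICP iterations, final RMS %.1f um, %d/%d points beyond "
        "tolerance", test_id, reference_id, icp.iterations, icp.rms * MM_TO_UM,
        fld.discarded_count, fld.sampled_count,
    )
    if fld.discarded_count > 0.01 * fld.sampled_count:
        logger.warning(
            "%s vs %s: %.1f%% of measurement points beyond the %.1f mm "
            "tolerance", test_id, reference_id,
            100.0 * fld.discarded_count / fld.sampled_count, config.tolerance_mm,
        )
    return fld, icp


def trueness_analysis(
    reference: TriangleMesh,
    tests: Sequence[TriangleMesh],
    config: ComparisonConfig | None = None,
    label: str = "trueness",
    test_ids: Sequence[str] | None = None,
) -> GroupResult:
    """Trueness design: each test scan against the designated reference object.

    One full align -> trim -> measure -> summarize chain per test mesh; the
    aggregate is the mean ± SD (and min/max/median) over the per-mesh
    absolute means and RMSEs.
    """
    if len(tests) < 1:
        raise ParameterError("need at least one test mesh")
    cfg = config or ComparisonConfig()
    index = SpatialIndex(reference)
    result = GroupResult(label=label, summaries=[])
    for i, test in enumerate(tests):
        tid = test_ids[i] if test_ids else f"{label}[{i}]"
        fld, icp = compare_pair(
            test, reference, cfg, reference_index=index,
            reference_id=label, test_id=tid,
        )
        result.summaries.append(
            summarize(fld, cfg.lower_q, cfg.upper_q, cfg.trim_on_absolute)
        )
        result.icp_results.append(icp)
        result.comparison_labels.append(tid)
        result.discarded_counts.append(fld.discarded_count)
    return result


def paired_trueness_analysis(
    references: Sequence[TriangleMesh],
    tests: Sequence[TriangleMesh],
    config: ComparisonConfig | None = None,
    label: str = "paired",
) -> GroupResult:
    """Paired trueness design: test scan i against reference scan i.

    Used when two workflow stages share replicates (e.g. each printed cast
    is compared to the intraoral scan it was printed from, the intraoral
    scan acting as the reference object).
    """
    if len(references) != len(tests) or not references:
        raise ParameterError("need equally many non-empty references and tests")
    cfg = config or ComparisonConfig()
    result = GroupResult(label=label, summaries=[])
    for i, (ref, test) in enumerate(zip(references, tests)):
        fld, icp = compare_pair(
            test, ref, cfg, reference_id=f"{label}-ref[{i}]", test_id=f"{label}[{i}]"
        )
        result.summaries.append(
            summarize(fld, cfg.lower_q, cfg.upper_q, cfg.trim_on_absolute)
        )
        result.icp_results.append(icp)
        result.comparison_labels.append(str(i))
        result.discarded_counts.append(fld.discarded_count)
    return result


def precision_analysis(
    group: Sequence[TriangleMesh],
    config: ComparisonConfig | None = None,
    label: str = "precision",
) -> GroupResult:
    """Precision design: all unordered pairs within one group.

    For every pair (i < j), scan i is the reference object and scan j the
    test, giving n(n-1)/2 superimpositions (45 for n = 10).
    """
    n = len(group)
    if n < 2:
        raise ParameterError("precision analysis needs at least two scans")
    cfg = config or ComparisonConfig()
    result = GroupResult(label=label, summaries=[])
    for i in range(n):
        index: SpatialIndex | None = None
        for j in range(i + 1, n):
            if index is None:
                index = SpatialIndex(group[i])
            fld, icp = compare_pair(
                group[j], group[i], cfg, reference_index=index,
                reference_id=f"{label}[{i}]", test_id=f"{label}[{j}]",
            )
            result.summaries.append(
                summarize(fld, cfg.lower_q, cfg.upper_q, cfg.trim_on_absolute)
            )
            result.icp_results.append(icp)
            result.comparison_labels.append(f"{i}-{j}")
            result.discarded_counts.append(fld.discarded_count)
    assert len(result.summaries) == n * (n - 1) // 2
    return result


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class StatTestResult:
    """One two-sample test with optional Bonferroni correction."""

    test_name: str
    statistic: float
    p_value: float
    p_corrected: float
    alpha: float
    correction_factor: float
    significant: bool
    shapiro_p: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 and 0.0 <= self.p_corrected <= 1.0):
            raise ParameterError("p-values must lie in [0, 1]")


def _shapiro_p(x: np.ndarray) -> float:
    # a constant sample carries no evidence against normality
    if np.ptp(x) == 0:
        return 1.0
    return float(_stats.shapiro(x).pvalue)


def compare_groups(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    paired: bool = False,
    alpha: float = 0.05,
    correction_factor: float = 1.0,
) -> StatTestResult:
    """Two-sample comparison with a Shapiro-Wilk normality gate.

    Both samples normal (Shapiro-Wilk p > 0.05) -> t-test (paired or
    independent); otherwise Mann-Whitney U for independent samples or the
    Wilcoxon signed-rank test for paired samples (two-tailed throughout).
    The p-value is multiplied by ``correction_factor`` (Bonferroni; pass the
    family size explicitly) and capped at 1.  Identical paired samples give
    the conventional p = 1.
    """
    x = np.asarray(a, float).ravel()
    y = np.asarray(b, float).ravel()
    if len(x) < 3 or len(y) < 3:
        raise ParameterError("each sample needs at least 3 observations")
    if paired and len(x) != len(y):
        raise ParameterError("paired samples must have equal length")
    if correction_factor < 1:
        raise ParameterError("correction factor must be >= 1")
    sp = (_shapiro_p(x), _shapiro_p(y))
    normal = sp[0] > 0.05 and sp[1] > 0.05
    if normal:
        if paired:
            if np.ptp(x - y) == 0 and np.all(x == y):
                name, stat, p = "t-test (paired)", 0.0, 1.0
            else:
                r = _stats.ttest_rel(x, y)
                name, stat, p = "t-test (paired)", float(r.statistic), float(r.pvalue)
        else:
            r = _stats.ttest_ind(x, y)
            name, stat, p = "t-test (independent)", float(r.statistic), float(r.pvalue)
    elif paired:
        d = x - y
        if np.all(d == 0):
            name, stat, p = "Wilcoxon signed-rank", 0.0, 1.0
        else:
            r = _stats.wilcoxon(x, y)
            name, stat, p = "Wilcoxon signed-rank", float(r.statistic), float(r.pvalue)
    else:
        r = _stats.mannwhitneyu(x, y, alternative="two-sided")
        name, stat, p = "Mann-Whitney U", float(r.statistic), float(r.pvalue)
    if np.isnan(p):  # degenerate zero-variance t-test
        p = 1.0
    p_corr = min(p * correction_factor, 1.0)
    return StatTestResult(
        test_name=name,
        statistic=stat,
        p_value=p,
        p_corrected=p_corr,
        alpha=alpha,
        correction_factor=correction_factor,
        significant=bool(p_corr <= alpha),
        shapiro_p=sp,
    )
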