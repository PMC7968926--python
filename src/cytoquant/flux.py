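"""Ca2+ reporter flux scoring and deposit-gated response statistics.

A reporter cell's intensity series is min-max normalized to [0, 100];
flux events are maximal supra-threshold runs (default threshold 50),
with runs separated by less than the merge window (default 20 s)
counted as a single event — sustained fluorescence over 20 s is one
flux, not several. Per-cell metrics are the event rate per minute, the
total time above threshold, and — when ligand-deposit times are known —
the proportion of time in flux inside versus outside the 20 s
post-deposit response windows. Cells that never flux are excluded.

Inference follows the nonparametric design of the assay: a Wilcoxon
rank-sum test contrasts the flux-time proportion between conditions,
and a Wilcoxon signed-rank test contrasts each cell's in-window against
its own out-of-window proportion (self-paired). Exact null
distributions are used for small samples without ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import DegenerateTraceError, ParameterError
from .io import TraceTable

__all__ = [
    "NormalizedTrace",
    "FluxEvent",
    "DepositWindowSet",
    "FluxCellSummary",
    "WindowProportions",
    "TestResult",
    "normalize_trace",
    "detect_flux_events",
    "flux_rate",
    "total_flux_time",
    "window_proportions",
    "percentile_bracket",
    "validate_threshold",
    "exclude_no_flux_cells",
    "rank_sum_test",
    "signed_rank_test",
    "flux_pipeline",
    "FluxPipelineResult",
]


@dataclass(frozen=True)
class NormalizedTrace:
    """A per-cell intensity series rescaled so min = 0 and max = 100."""

    cell_id: str
    time: np.ndarray
    value: np.ndarray

    @property
    def dt(self) -> float:
        """Sampling interval, taken as the median time step."""
        return float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        """Acquisition duration: n_samples x dt."""
        return len(self.time) * self.dt


@dataclass(frozen=True)
class FluxEvent:
    """One supra-threshold Ca2+ episode."""

    t_start: float
    t_end: float
    peak_value: float
    peak_time: float


@dataclass(frozen=True)
class DepositWindowSet:
    """Post-deposit response windows [d, d + window] for one cell."""

    deposit_times: tuple[float, ...]
    window: float = 20.0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ParameterError(f"window must be positive, got {self.window}")
        object.__setattr__(
            self, "deposit_times", tuple(sorted(float(t) for t in self.deposit_times))
        )

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask of sample times inside the union of windows."""
        times = np.asarray(times, dtype=float)
        inside = np.zeros(times.shape, dtype=bool)
        for d in self.deposit_times:
            inside |= (times >= d) & (times <= d + self.window)
        return inside


@dataclass(frozen=True)
class WindowProportions:
    """Flux-time proportions inside/outside the deposit windows.

    ``prop_in``/``prop_out`` are NaN when the corresponding time base is
    empty (no windows, or windows covering the whole acquisition); the
    ``*_defined`` flags say which side is meaningful.
    """

    prop_in: float
    prop_out: float
    in_defined: bool
    out_defined: bool


@dataclass(frozen=True)
class FluxCellSummary:
    cell_id: str
    condition: str
    n_events: int
    flux_rate: float            # events / min
    total_flux_time: float      # seconds above threshold
    duration: float             # seconds
    prop_flux: float            # total_flux_time / duration
    prop_in_windows: float      # NaN when no deposit windows
    prop_out_windows: float
    has_deposits: bool


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str                 # "exact" | "approximate"
    n: tuple[int, ...]
    degenerate: bool = False


def normalize_trace(
    times: np.ndarray, values: np.ndarray, cell_id: str = ""
) -> NormalizedTrace:
    """Rescale a raw trace so its minimum maps to 0 and maximum to 100.

    Raises :class:`DegenerateTraceError` for constant traces, where the
    rescale is undefined.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ParameterError("trace needs >= 2 samples")
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi <= lo:
        raise DegenerateTraceError(
            f"trace {cell_id!r} is constant (min == max == {lo}); "
            "min-max normalization undefined"
        )
    return NormalizedTrace(cell_id, times, 100.0 * (values - lo) / (hi - lo))


def detect_flux_events(
    trace: NormalizedTrace,
    threshold: float = 50.0,
    merge_window: float = 20.0,
) -> list[FluxEvent]:
    """Detect flux events as merged supra-threshold runs.

    Candidate episodes are maximal contiguous runs of samples with
    ``value >= threshold``; consecutive episodes whose gap (end of one
    to start of the next) is shorter than ``merge_window`` seconds are
    merged, so maintained or briefly interrupted fluorescence counts as
    a single flux regardless of its duration.
    """
    if not 0 < threshold <= 100:
        raise ParameterError(f"threshold must lie in (0, 100], got {threshold}")
    if merge_window < 0:
        raise ParameterError("merge_window must be non-negative")
    above = trace.value >= threshold
    if not np.any(above):
        return []
    # maximal runs of consecutive supra-threshold samples
    padded = np.diff(np.concatenate([[0], above.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    runs = list(zip(starts, ends))
    # gap-merge: end-to-start time below merge_window joins episodes
    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if trace.time[s] - trace.time[merged[-1][1]] < merge_window:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        seg = trace.value[s : e + 1]
        k = int(np.argmax(seg)) + s
        events.append(
            FluxEvent(
                t_start=float(trace.time[s]),
                t_end=float(trace.time[e]),
                peak_value=float(trace.value[k]),
                peak_time=float(trace.time[k]),
            )
        )
    return events


def flux_rate(events: Sequence[FluxEvent] | int, duration: float) -> float:
    """Events per minute over an acquisition of ``duration`` seconds."""
    if duration <= 0:
        raise ParameterError(f"duration must be positive, got {duration}")
    n = events if isinstance(events, int) else len(events)
    return n / (duration / 60.0)


def total_flux_time(trace: NormalizedTrace, threshold: float = 50.0) -> float:
    """Seconds with normalized value strictly greater than ``threshold``.

    Computed as (number of supra-threshold samples) x dt.
    """
    return float(np.count_nonzero(trace.value > threshold)) * trace.dt


def window_proportions(
    trace: NormalizedTrace,
    windows: DepositWindowSet,
    threshold: float = 50.0,
) -> WindowProportions:
    """Proportion of time in flux inside vs outside the deposit windows.

    ``prop_in`` is the supra-threshold fraction of samples inside the
    union of [d, d + window] response windows; ``prop_out`` the fraction
    over the complement of that union within the acquisition.
    """
    supra = trace.value > threshold
    inside = windows.contains(trace.time)
    n_in = int(inside.sum())
    n_out = int((~inside).sum())
    prop_in = float(np.count_nonzero(supra & inside)) / n_in if n_in else float("nan")
    prop_out = (
        float(np.count_nonzero(supra & ~inside)) / n_out if n_out else float("nan")
    )
    return WindowProportions(prop_in, prop_out, n_in > 0, n_out > 0)


def percentile_bracket(
    control_values: np.ndarray, lo: float = 90.0, hi: float = 95.0
) -> tuple[float, float]:
    """Percentile bracket of the pooled control flux-value distribution.

    Returns the ``lo``-th and ``hi``-th percentiles under linear
    interpolation between order statistics. A threshold is considered
    validated when it lies between the two (see
    :func:`validate_threshold`).
    """
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size < 2:
        raise ParameterError("need >= 2 control values")
    if not 0 < lo < hi < 100:
        raise ParameterError(f"need 0 < lo < hi < 100, got lo={lo}, hi={hi}")
    p_lo, p_hi = np.percentile(control_values, [lo, hi], method="linear")
    return float(p_lo), float(p_hi)


def validate_threshold(threshold: float, p_lo: float, p_hi: float) -> bool:
    """True when the flux threshold lies within the control percentile
    bracket, i.e. P_lo <= threshold <= P_hi."""
    return p_lo <= threshold <= p_hi


def exclude_no_flux_cells(
    summaries: Sequence[FluxCellSummary],
) -> tuple[list[FluxCellSummary], list[str]]:
    """Drop cells that never fluxed during the time-lapse.

    Returns the retained summaries and the ids of the excluded cells.
    """
    kept = [s for s in summaries if s.n_events > 0]
    excluded = [s.cell_id for s in summaries if s.n_events == 0]
    return kept, excluded


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the combined sample size is
    <= 25 and there are no ties; otherwise the normal approximation
    with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be nonempty")
    exact = (x.size + y.size) <= 25 and not _has_ties(np.concatenate([x, y]))
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(min(1.0, res.pvalue)),
        method="exact" if exact else "approximate",
        n=(int(x.size), int(y.size)),
    )


def signed_rank_test(
    pairs: Sequence[tuple[float, float]],
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired proportions.

    Differences are first - second per pair; zero differences are
    dropped (standard convention). The exact null is used for n <= 25
    non-zero differences without ties among their absolute values;
    otherwise the normal approximation with tie correction. If every
    difference is zero the result is p = 1 with the degenerate flag set.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ParameterError("pairs must be a nonempty sequence of 2-tuples")
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    if d.size == 0:
        return TestResult(0.0, 1.0, "exact", (0,), degenerate=True)
    exact = d.size <= 25 and not _has_ties(np.abs(d))
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(min(1.0, res.pvalue)),
        method="exact" if exact else "approximate",
        n=(int(d.size),),
    )


@dataclass(frozen=True)
class FluxPipelineResult:
    summaries: pd.DataFrame
    excluded_cells: list[str]
    condition_test: TestResult | None
    deposit_test: TestResult | None
    percentiles: tuple[float, float] | None
    threshold_validated: bool | None
    config: dict = field(default_factory=dict)

    def tests_dict(self) -> dict:
        """JSON-ready summary of the statistical comparisons."""
        out: dict = {"config": self.config, "excluded_cells": self.excluded_cells}
        if self.condition_test is not None:
            t = self.condition_test
            out["rank_sum_condition_contrast"] = {
                "statistic": t.statistic, "p": t.pvalue,
                "n": list(t.n), "method": t.method,
            }
        if self.deposit_test is not None:
            t = self.deposit_test
            out["signed_rank_deposit_contrast"] = {
                "statistic": t.statistic, "p": t.pvalue,
                "n": list(t.n), "method": t.method, "degenerate": t.degenerate,
            }
        if self.percentiles is not None:
            out["control_percentile_bracket"] = {
                "p_lo": self.percentiles[0], "p_hi": self.percentiles[1],
                "threshold_validated": self.threshold_validated,
            }
        return out


def summarize_cell(
    cell_id: str,
    condition: str,
    times: np.ndarray,
    values: np.ndarray,
    config: AnalysisConfig,
    deposit_times: Sequence[float] | None = None,
) -> FluxCellSummary:
    """Normalize one raw trace and compute its per-cell flux metrics."""
    norm = normalize_trace(times, values, cell_id)
    events = detect_flux_events(norm, config.flux_threshold, config.merge_window)
    tft = total_flux_time(norm, config.flux_threshold)
    duration = norm.duration
    if deposit_times:
        windows = DepositWindowSet(tuple(deposit_times), config.response_window)
        props = window_proportions(norm, windows, config.flux_threshold)
        prop_in, prop_out = props.prop_in, props.prop_out
        has_dep = True
    else:
        prop_in, prop_out, has_dep = float("nan"), float("nan"), False
    return FluxCellSummary(
        cell_id=cell_id,
        condition=condition,
        n_events=len(events),
        flux_rate=flux_rate(len(events), duration),
        total_flux_time=tft,
        duration=duration,
        prop_flux=tft / duration,
        prop_in_windows=prop_in,
        prop_out_windows=prop_out,
        has_deposits=has_dep,
    )


def flux_pipeline(
    traces: TraceTable,
    deposits: dict[str, Sequence[float]] | None,
    config: AnalysisConfig | None = None,
    case_condition: str | None = None,
    control_condition: str | None = None,
) -> FluxPipelineResult:
    """Run the full flux analysis.

    Stages: per-cell min-max normalization -> event detection ->
    per-cell metrics -> exclusion of cells without any flux ->
    rank-sum contrast of flux-time proportion between case and control
    conditions -> signed-rank contrast of in-window vs out-of-window
    proportion over deposit-bearing cells -> percentile bracketing of
    the pooled control values against the configured threshold.

    ``deposits`` maps cell id to deposit times in seconds; cells absent
    from the map have no response windows. When the condition labels are
    not given, a two-condition table is contrasted in sorted label order
    (first = case is arbitrary; the test is two-sided).
    """
    config = config or AnalysisConfig()
    deposits = deposits or {}
    summaries = [
        summarize_cell(cell_id, cond, t, v, config, deposits.get(cell_id))
        for cell_id, cond, t, v in traces.iter_cells()
    ]
    kept, excluded = exclude_no_flux_cells(summaries)

    df = pd.DataFrame([s.__dict__ for s in kept])

    condition_test = None
    percentiles = None
    validated = None
    conditions = sorted({s.condition for s in kept})
    if case_condition is None and control_condition is None and len(conditions) == 2:
        control_condition, case_condition = conditions[0], conditions[1]
    if case_condition is not None and control_condition is not None:
        x = [s.prop_flux for s in kept if s.condition == case_condition]
        y = [s.prop_flux for s in kept if s.condition == control_condition]
        if x and y:
            condition_test = rank_sum_test(x, y)
        # pooled control distribution brackets the threshold
        pooled = []
        for s in traces.iter_cells():
            if s[1] == control_condition:
                norm = normalize_trace(s[2], s[3], s[0])
                pooled.append(norm.value)
        if pooled:
            pooled_arr = np.concatenate(pooled)
            percentiles = percentile_bracket(
                pooled_arr, config.percentile_lo, config.percentile_hi
            )
            validated = validate_threshold(config.flux_threshold, *percentiles)

    deposit_test = None
    pairs = [
        (s.prop_in_windows, s.prop_out_windows)
        for s in kept
        if s.has_deposits
        and np.isfinite(s.prop_in_windows)
        and np.isfinite(s.prop_out_windows)
    ]
    if pairs:
        deposit_test = signed_rank_test(pairs)

    return FluxPipelineResult(
        summaries=df,
        excluded_cells=excluded,
        condition_test=condition_test,
        deposit_test=deposit_test,
        percentiles=percentiles,
        threshold_validated=validated,
        config=config.to_dict(),
    )
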