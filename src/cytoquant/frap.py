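"""FRAP-based estimation of transport velocity to cytoneme tips.

Photobleach a cytoneme, record recovery of fluorescence at regions of
interest (ROIs) a known distance from the cell body, and the halftime
of recovery gives a transport velocity::

    v = distance from cell body (um) / tau_1/2 (s)

Curves are first corrected for fluorescence lost to imaging itself
(dividing by a matched unbleached reference region), normalized so the
pre-bleach baseline is 100% and the first post-bleach frame 0%, and fit
with a single-exponential recovery toward a plateau,
``R(t) = P * (1 - 2**(-t/tau))``, whose ``tau`` is the halftime by
construction. ROIs whose fitted plateau stays below a cutoff (default
20%) are classified as failed recoveries — the behaviour of
ionomycin-treated cytonemes where tip-ward transport is blocked.
Velocities of the 2-3 ROIs along one cytoneme are averaged per
cytoneme before any condition-level comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import AnalysisConfig
from .errors import ParameterError, ValidationError

__all__ = [
    "FrapRoi",
    "FrapRecord",
    "bleach_correct",
    "normalize_frap",
    "estimate_halftime",
    "halftime_by_crossing",
    "roi_velocity",
    "cytoneme_mean_velocity",
    "frap_pipeline",
    "FrapPipelineResult",
]


@dataclass(frozen=True)
class FrapRoi:
    """One bleached region's fitted recovery."""

    roi_id: str
    distance: float              # um from the cell body
    tau_half: float              # s; NaN when not recovered
    plateau: float               # % of pre-bleach
    velocity: float              # um/s; NaN when not recovered
    recovered: bool
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FrapRecord:
    """Per-cytoneme aggregate of its ROIs."""

    cytoneme_id: str
    condition: str
    rois: tuple[FrapRoi, ...]
    mean_velocity: float         # um/s; NaN when no ROI recovered
    recovered: bool


def bleach_correct(
    frap_trace: np.ndarray, reference: np.ndarray, n_prebleach: int
) -> np.ndarray:
    """Correct a FRAP trace for fluorescence loss during acquisition.

    ``corrected_i = frap_i * (mean prebleach reference / reference_i)``
    using the first ``n_prebleach`` reference samples as the pre-bleach
    level. A constant reference leaves the trace unchanged; a reference
    decaying as ``exp(-b t)`` cancels the same decay in the FRAP ROI.
    """
    frap_trace = np.asarray(frap_trace, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frap_trace.shape != reference.shape:
        raise ValidationError(
            f"trace length {frap_trace.size} != reference length {reference.size}"
        )
    if n_prebleach < 1 or n_prebleach > reference.size:
        raise ParameterError("n_prebleach outside the trace")
    bad = np.flatnonzero(reference <= 0)
    if bad.size:
        raise ValidationError(
            f"reference non-positive at frame {int(bad[0])}"
        )
    pre = float(np.mean(reference[:n_prebleach]))
    return frap_trace * (pre / reference)


def normalize_frap(
    corrected: np.ndarray,
    times: np.ndarray,
    t0: float,
    pre_window: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a corrected trace to percent recovery.

    100% is the mean over the pre-bleach window (the ``pre_window``
    seconds preceding the bleach at ``t0``); 0% is the first
    post-bleach sample. Returns ``(post_bleach_times_rebased_to_0,
    percent_recovery)`` for the post-bleach portion.
    """
    corrected = np.asarray(corrected, dtype=float)
    times = np.asarray(times, dtype=float)
    pre_mask = (times < t0) & (times >= t0 - pre_window)
    post_mask = times >= t0
    if pre_mask.sum() < 2:
        raise ParameterError("need >= 2 pre-bleach samples in the window")
    if post_mask.sum() < 1:
        raise ParameterError("need >= 1 post-bleach sample")
    pre_level = float(np.mean(corrected[pre_mask]))
    post = corrected[post_mask]
    post_times = times[post_mask] - t0
    floor = float(post[0])
    if pre_level == floor:
        raise ParameterError(
            "pre-bleach mean equals first post-bleach value; "
            "normalization degenerate"
        )
    return post_times, 100.0 * (post - floor) / (pre_level - floor)


def _recovery_model(t: np.ndarray, plateau: float, tau: float) -> np.ndarray:
    return plateau * (1.0 - np.power(2.0, -t / tau))


def estimate_halftime(
    times: np.ndarray,
    percent: np.ndarray,
    plateau_cutoff: float = 20.0,
) -> tuple[float, float, dict]:
    """Fit ``R(t) = P * (1 - 2**(-t/tau))`` to a % recovery curve.

    ``times`` are seconds since the bleach. Returns
    ``(tau_half, plateau, diagnostics)``; ``tau_half`` is NaN and
    ``diagnostics["recovered"]`` False when the fitted plateau is below
    ``plateau_cutoff`` percent or the fit fails to converge. No
    exception is raised for non-convergence.
    """
    times = np.asarray(times, dtype=float)
    percent = np.asarray(percent, dtype=float)
    if times.size < 10:
        raise ParameterError("need >= 10 post-bleach samples to fit")
    p_guess = max(float(np.mean(percent[-max(5, times.size // 10):])), 1.0)
    half = p_guess / 2.0
    above = np.flatnonzero(percent >= half)
    tau_guess = float(times[above[0]]) if above.size else float(times[-1] / 2)
    tau_guess = max(tau_guess, float(np.min(np.diff(times))))
    try:
        popt, pcov = optimize.curve_fit(
            _recovery_model,
            times,
            percent,
            p0=(p_guess, tau_guess),
            bounds=([0.0, 1e-6], [300.0, 1e5]),
            maxfev=5000,
        )
        plateau, tau = float(popt[0]), float(popt[1])
        resid = percent - _recovery_model(times, *popt)
        diag = {
            "converged": True,
            "rmse": float(np.sqrt(np.mean(resid**2))),
            "plateau_se": float(np.sqrt(pcov[0, 0])),
            "tau_se": float(np.sqrt(pcov[1, 1])),
        }
    except (RuntimeError, ValueError) as exc:
        diag = {"converged": False, "error": str(exc)}
        plateau, tau = float("nan"), float("nan")
    if diag["converged"]:
        # classify on the recovery actually achieved within the
        # acquisition: an extrapolated plateau with tau far beyond the
        # recording is a degenerate fit of noise, not a recovery
        achieved = plateau * (1.0 - 2.0 ** (-float(times[-1]) / tau))
        diag["achieved_pct"] = float(achieved)
        recovered = min(plateau, achieved) >= plateau_cutoff
    else:
        recovered = False
    diag["recovered"] = recovered
    if not recovered:
        tau = float("nan")
    return tau, plateau, diag


def halftime_by_crossing(times: np.ndarray, percent: np.ndarray) -> float:
    """Model-free halftime: first time the curve crosses 50% of its
    terminal plateau (mean of the last tenth of samples). A cross-check
    for the exponential fit, noisier on real curves."""
    times = np.asarray(times, dtype=float)
    percent = np.asarray(percent, dtype=float)
    plateau = float(np.mean(percent[-max(2, times.size // 10):]))
    above = np.flatnonzero(percent >= plateau / 2.0)
    return float(times[above[0]]) if above.size else float("nan")


def roi_velocity(distance: float, tau_half: float) -> float:
    """Transport velocity of one ROI: ``v = distance / tau_half``."""
    if distance <= 0:
        raise ParameterError(f"distance must be positive, got {distance}")
    if not tau_half > 0:
        raise ParameterError(f"tau_half must be positive, got {tau_half}")
    return distance / tau_half


def cytoneme_mean_velocity(rois: list[FrapRoi]) -> float:
    """Arithmetic mean ROI velocity over the recovered ROIs of one
    cytoneme; NaN when none recovered."""
    vs = [r.velocity for r in rois if r.recovered and np.isfinite(r.velocity)]
    return float(np.mean(vs)) if vs else float("nan")


@dataclass(frozen=True)
class FrapPipelineResult:
    roi_table: pd.DataFrame
    cytoneme_table: pd.DataFrame
    comparison: dict
    config: dict = field(default_factory=dict)


def _analyze_roi(
    roi_id: str,
    distance: float,
    t0: float,
    times: np.ndarray,
    intensity: np.ndarray,
    reference: np.ndarray | None,
    config: AnalysisConfig,
) -> FrapRoi:
    n_pre = int(np.count_nonzero(times < t0))
    if reference is not None:
        corrected = bleach_correct(intensity, reference, max(n_pre, 1))
    else:
        corrected = np.asarray(intensity, dtype=float)
    post_t, percent = normalize_frap(
        corrected, times, t0, config.pre_bleach_window
    )
    tau, plateau, diag = estimate_halftime(
        post_t, percent, config.plateau_cutoff
    )
    recovered = bool(diag["recovered"])
    velocity = roi_velocity(distance, tau) if recovered else float("nan")
    return FrapRoi(roi_id, distance, tau, plateau, velocity, recovered, diag)


def frap_pipeline(
    records: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> FrapPipelineResult:
    """Run the full FRAP analysis on a long-format table.

    Required columns: ``cytoneme_id``, ``roi_id``, ``condition``,
    ``distance_um``, ``t0_s``, ``time_s``, ``intensity``; optional
    ``reference`` (matched unbleached region) enables acquisition-bleach
    correction. Stages: correct -> normalize -> fit -> per-ROI velocity
    -> per-cytoneme mean -> per-condition summary (mean +/- SD, n,
    non-recovery fraction) and a two-tailed t-test between conditions
    when exactly two have recovered cytonemes.
    """
    config = config or AnalysisConfig()
    required = {
        "cytoneme_id", "roi_id", "condition", "distance_um", "t0_s",
        "time_s", "intensity",
    }
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"FRAP table missing columns {sorted(missing)}")
    roi_rows = []
    records_by_cyt: dict[tuple[str, str], list[FrapRoi]] = {}
    for (cond, cyt, roi), sub in records.groupby(
        ["condition", "cytoneme_id", "roi_id"], sort=False
    ):
        sub = sub.sort_values("time_s")
        cond = str(cond)
        ref = (
            sub["reference"].to_numpy(dtype=float)
            if "reference" in sub.columns and sub["reference"].notna().all()
            else None
        )
        fr = _analyze_roi(
            str(roi),
            float(sub["distance_um"].iloc[0]),
            float(sub["t0_s"].iloc[0]),
            sub["time_s"].to_numpy(dtype=float),
            sub["intensity"].to_numpy(dtype=float),
            ref,
            config,
        )
        records_by_cyt.setdefault((str(cyt), cond), []).append(fr)
        roi_rows.append(
            {
                "cytoneme_id": cyt, "roi_id": roi, "condition": cond,
                "distance_um": fr.distance, "tau_half_s": fr.tau_half,
                "plateau_pct": fr.plateau, "velocity_um_per_s": fr.velocity,
                "recovered": fr.recovered,
            }
        )
    cyt_rows = []
    for (cyt, cond), rois in records_by_cyt.items():
        rois_sorted = tuple(sorted(rois, key=lambda r: r.distance))
        mv = cytoneme_mean_velocity(list(rois_sorted))
        cyt_rows.append(
            {
                "cytoneme_id": cyt, "condition": cond,
                "n_rois": len(rois_sorted),
                "n_recovered": sum(r.recovered for r in rois_sorted),
                "mean_velocity_um_per_s": mv,
                "recovered": bool(np.isfinite(mv)),
            }
        )
    roi_df = pd.DataFrame(roi_rows)
    cyt_df = pd.DataFrame(cyt_rows)

    comparison: dict = {"conditions": {}}
    for cond, sub in cyt_df.groupby("condition"):
        vs = sub.loc[sub["recovered"], "mean_velocity_um_per_s"].to_numpy()
        comparison["conditions"][cond] = {
            "n_cytonemes": int(len(sub)),
            "n_recovered": int(sub["recovered"].sum()),
            "non_recovery_fraction": float(1.0 - sub["recovered"].mean()),
            "mean_velocity_um_per_s": float(np.mean(vs)) if vs.size else None,
            "sd_velocity_um_per_s": (
                float(np.std(vs, ddof=1)) if vs.size > 1 else None
            ),
        }
    recovered_conds = [
        c for c, d in comparison["conditions"].items() if d["n_recovered"] >= 2
    ]
    if len(recovered_conds) == 2:
        a, b = sorted(recovered_conds)
        va = cyt_df.loc[
            (cyt_df["condition"] == a) & cyt_df["recovered"],
            "mean_velocity_um_per_s",
        ]
        vb = cyt_df.loc[
            (cyt_df["condition"] == b) & cyt_df["recovered"],
            "mean_velocity_um_per_s",
        ]
        t, p = stats.ttest_ind(va, vb)
        comparison["t_test"] = {
            "conditions": [a, b], "statistic": float(t), "p": float(p),
            "significant": bool(p < config.alpha),
        }
    return FrapPipelineResult(roi_df, cyt_df, comparison, config.to_dict())
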