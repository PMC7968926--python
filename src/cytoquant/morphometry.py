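"""Cytoneme scoring, occurrence statistics, and group comparisons.

A projection is scored as a cytoneme when it is at least 10 um long, at
most 0.2 um (200 nm) wide, and does not maintain continuous contact
with the coverslip (substrate-attached protrusions are excluded). The
occurrence rate is the percentage of scored cells bearing at least one
cytoneme, reported with a Wilson binomial confidence interval.

Group comparisons follow the assay's conventions: a two-tailed Student
t-test for two groups, one-way ANOVA with Tukey HSD post-test for more
than two, with significance stars at 0.05 / 0.01 / 0.001 / 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.proportion import proportion_confint

from .config import AnalysisConfig
from .errors import ParameterError
from .simulate import OccurrenceSample

__all__ = [
    "ProjectionRecord",
    "IntensityRatio",
    "score_projection",
    "occurrence_rate",
    "intensity_ratio",
    "compare_groups",
    "significance_stars",
]


@dataclass(frozen=True)
class ProjectionRecord:
    """One measured cellular projection."""

    cell_id: str
    length: float                  # um
    width: float                   # um
    substrate_attached: bool = False
    motile: bool | None = None     # live-imaging metadata, not computed here

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ParameterError("length and width must be positive")


@dataclass(frozen=True)
class IntensityRatio:
    cell_id: str
    cytoneme_mean: float
    body_mean: float
    ratio: float
    defined: bool


def score_projection(
    rec: ProjectionRecord, config: AnalysisConfig | None = None
) -> bool:
    """True iff the projection qualifies as a cytoneme: length >=
    ``min_cytoneme_length``, width <= ``max_cytoneme_width``, and not
    substrate-attached."""
    config = config or AnalysisConfig()
    return (
        rec.length >= config.min_cytoneme_length
        and rec.width <= config.max_cytoneme_width
        and not rec.substrate_attached
    )


def occurrence_rate(
    sample: OccurrenceSample, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Occurrence rate in percent with its Wilson confidence interval.

    Returns ``(rate_percent, (ci_lo_percent, ci_hi_percent))``.
    """
    if sample.n_cells_scored < 1:
        raise ParameterError("no cells scored")
    rate = 100.0 * sample.n_cells_with_cytoneme / sample.n_cells_scored
    lo, hi = proportion_confint(
        sample.n_cells_with_cytoneme,
        sample.n_cells_scored,
        alpha=alpha,
        method="wilson",
    )
    return rate, (100.0 * float(lo), 100.0 * float(hi))


def intensity_ratio(
    cytoneme_pixels: np.ndarray,
    body_pixels: np.ndarray,
    cell_id: str = "",
) -> IntensityRatio:
    """Mean cytoneme-to-cell-body fluorescence ratio for one cell.

    Both pixel sets must have at least 10 pixels; a zero body mean
    yields an undefined, flagged ratio.
    """
    c = np.asarray(cytoneme_pixels, dtype=float)
    b = np.asarray(body_pixels, dtype=float)
    if c.size < 10 or b.size < 10:
        raise ParameterError("both pixel sets need >= 10 pixels")
    cm, bm = float(np.mean(c)), float(np.mean(b))
    if bm == 0:
        return IntensityRatio(cell_id, cm, bm, float("nan"), defined=False)
    return IntensityRatio(cell_id, cm, bm, cm / bm, defined=True)


def significance_stars(p: float, alpha: float = 0.05) -> str:
    """Star notation at the conventional levels."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < alpha:
        return "*"
    return "ns"


def compare_groups(
    samples: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> dict:
    """Compare measurement groups.

    Two groups: two-tailed Student t-test. More than two: one-way ANOVA
    with Tukey HSD pairwise post-test. Returns a JSON-ready report with
    p-values and significance stars.
    """
    if len(samples) < 2:
        raise ParameterError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ParameterError(f"group {name!r} has n < 2")
    names = sorted(arrays)
    report: dict = {
        "groups": {
            name: {
                "n": int(arrays[name].size),
                "mean": float(np.mean(arrays[name])),
                "sd": float(np.std(arrays[name], ddof=1)),
            }
            for name in names
        }
    }
    if len(names) == 2:
        t, p = stats.ttest_ind(arrays[names[0]], arrays[names[1]])
        report["test"] = "two-tailed t-test"
        report["statistic"] = float(t)
        report["p"] = float(p)
        report["stars"] = significance_stars(float(p), alpha)
    else:
        f, p = stats.f_oneway(*(arrays[n] for n in names))
        report["test"] = "one-way ANOVA + Tukey HSD"
        report["statistic"] = float(f)
        report["p"] = float(p)
        report["stars"] = significance_stars(float(p), alpha)
        values = np.concatenate([arrays[n] for n in names])
        labels = np.concatenate(
            [np.full(arrays[n].size, n, dtype=object) for n in names]
        )
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        pairwise = []
        for row in tukey.summary().data[1:]:
            g1, g2, meandiff, p_adj, lower, upper, reject = row
            pairwise.append(
                {
                    "group1": str(g1), "group2": str(g2),
                    "mean_diff": float(meandiff), "p_adj": float(p_adj),
                    "ci": [float(lower), float(upper)],
                    "significant": bool(reject),
                    "stars": significance_stars(float(p_adj), alpha),
                }
            )
        report["tukey"] = pairwise
    return report
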