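"""Analysis configuration.

The constants of the quantification protocol live here: the normalized
flux threshold of 50, the 20 s gap-merge / deposit-response windows, the
90th/95th control percentile bracket, the cytoneme geometry criteria
(>= 10 um long, <= 0.2 um wide), the 1.5x-background puncta rule, and the
two-sided significance level alpha = 0.05.

Every result object carries a snapshot of the configuration that produced
it, for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of the analysis pipelines.

    Parameters
    ----------
    flux_threshold
        Minimum normalized fluorescence (0-100 scale) for a Ca2+ flux
        event. Default 50.
    merge_window
        Supra-threshold episodes separated by less than this many seconds
        are merged into a single flux event. Default 20 s.
    response_window
        Length in seconds of the post-deposit window in which a Ca2+
        response is attributed to the deposit. Default 20 s.
    percentile_lo, percentile_hi
        Percentile bracket of the pooled control distribution that the
        flux threshold must fall within. Defaults 90 and 95.
    min_cytoneme_length
        Minimum skeleton length in micrometres for a projection to be
        scored as a cytoneme. Default 10 um.
    max_cytoneme_width
        Maximum mean width in micrometres. Default 0.2 um (200 nm).
    puncta_factor
        A punctum must exceed this multiple of the local background
        fluorescence. Default 1.5 (i.e. >50% above background).
    alpha
        Two-sided significance level. Default 0.05.
    seed
        Seed for any stochastic step (none in the core pipelines; kept
        for provenance of simulated inputs).
    tip_zone
        Distance from the cytoneme tip (um) within which a terminating
        track counts as tip-arrived. Default 1.0 um.
    retro_deadband
        Displacement (um) below which frame-to-frame movement is treated
        as stationary rather than retrograde. Default 0.5 um.
    plateau_cutoff
        FRAP recoveries with a fitted plateau below this percentage are
        classified as failed. Default 20%.
    pre_bleach_window
        Length in seconds of the pre-bleach baseline used as the 100%
        anchor. Default 5 s.
    """

    flux_threshold: float = 50.0
    merge_window: float = 20.0
    response_window: float = 20.0
    percentile_lo: float = 90.0
    percentile_hi: float = 95.0
    min_cytoneme_length: float = 10.0
    max_cytoneme_width: float = 0.2
    puncta_factor: float = 1.5
    alpha: float = 0.05
    seed: int = 0
    tip_zone: float = 1.0
    retro_deadband: float = 0.5
    plateau_cutoff: float = 20.0
    pre_bleach_window: float = 5.0

    def __post_init__(self) -> None:
        positive = [
            "flux_threshold", "merge_window", "response_window",
            "percentile_lo", "percentile_hi", "min_cytoneme_length",
            "max_cytoneme_width", "puncta_factor", "alpha", "tip_zone",
            "retro_deadband", "plateau_cutoff", "pre_bleach_window",
        ]
        for name in positive:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"{name} must be numeric, got {value!r}")
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")
        if not self.percentile_lo < self.percentile_hi:
            raise ConfigError(
                "percentile_lo must be < percentile_hi "
                f"(got {self.percentile_lo} >= {self.percentile_hi})"
            )
        if not 0 < self.flux_threshold < 100:
            raise ConfigError(
                f"flux_threshold must lie in (0, 100), got {self.flux_threshold}"
            )
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")

    def to_dict(self) -> dict:
        """Snapshot of the configuration for embedding in result files."""
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key/value file.

    Unspecified keys take the defaults; unknown keys and non-numeric
    values raise :class:`~cytoquant.errors.ConfigError`. ``path=None``
    or an empty file yields the defaults.
    """
    if path is None:
        return AnalysisConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return AnalysisConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)
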