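"""Configuration objects for simulation, event detection, and pipeline runs.

All configs are plain dataclasses that validate on construction and
serialize to/from YAML, so a saved config reproduces a run exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic RFID feeder-visit study.

    The generator emulates a two-site field experiment: a multi-day
    baseline with a single familiar-food feeder per site, followed by two
    trials in which a novel-food feeder is paired with the familiar one.
    Birds carry a latent gregariousness that drives both flock joining and
    (configurably) novel-food preference.

    Parameters
    ----------
    n_individuals_per_site
        Tagged birds per site.
    n_sites
        Number of spatially disjoint sites (local populations).
    baseline_days, trial_days
        Days of baseline recording and of each experimental trial.
    day_length_s
        Foraging day length in seconds (dawn to dusk).
    events_per_site_day
        Poisson mean of flocking events per site per day.
    within_event_sd
        SD (seconds) of detection times around an event centre.
    between_event_gap_min
        Minimum gap (seconds) between consecutive event centres; must be
        at least 6x ``within_event_sd`` so bursts stay separable.
    detections_per_member
        Poisson mean of extra antenna reads per event member (each member
        emits at least one read).
    detection_rate_sd
        SD (log scale) of a per-bird lognormal multiplier on the read
        rate. Birds differ in how intensively they use a feeder per
        visit, independently of how social they are; without this, total
        detection counts would be a deterministic proxy of sociality.
    gregariousness_sd
        SD of the latent sociality trait (mean 0).
    join_intercept, join_slope
        Logit of the probability that a bird joins an event at its site:
        ``logit p = join_intercept + join_slope * gregariousness``.
    diet_intercept, diet_slope_sociality
        Logit of the per-read probability that a trial read lands on the
        novel feeder; the slope is the true sociality->novel-use effect.
    neophobia_slope_sociality
        Sociality effect on the *first* trial read only (whether a bird's
        first arrival is at the novel feeder). Default 0: first-arrival
        choice is independent of sociality even when usage is not.
    site_colour_effect
        Logit shift applied at sites whose novel food is dyed green
        (colour preference; the colours swap between trials).
    covariate_effects
        Optional logit effects of traits on novel use, keyed by
        ``sex`` (M), ``age`` (juvenile), ``immigrant`` (True). Default all 0.
    seed
        Master seed; identical configs give bit-identical output.
    """

    n_individuals_per_site: int = 40
    n_sites: int = 2
    baseline_days: int = 12
    trial_days: int = 4
    day_length_s: float = 28_800.0
    events_per_site_day: float = 30.0
    within_event_sd: float = 30.0
    between_event_gap_min: float = 300.0
    detections_per_member: float = 3.0
    detection_rate_sd: float = 0.6
    gregariousness_sd: float = 1.0
    join_intercept: float = -1.8
    join_slope: float = 0.5
    diet_intercept: float = -0.5
    diet_slope_sociality: float = 0.5
    neophobia_slope_sociality: float = 0.0
    site_colour_effect: float = -1.5
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    start_date: str = "2018-01-11"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals_per_site", "n_sites", "baseline_days",
                     "trial_days"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        for name in ("day_length_s", "events_per_site_day", "within_event_sd",
                     "between_event_gap_min", "gregariousness_sd"):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigError(f"{name} must be > 0, got {v!r}")
        if self.detections_per_member < 0:
            raise ConfigError(
                f"detections_per_member must be >= 0, got {self.detections_per_member!r}")
        if self.detection_rate_sd < 0:
            raise ConfigError(
                f"detection_rate_sd must be >= 0, got {self.detection_rate_sd!r}")
        if not self.within_event_sd < self.between_event_gap_min / 6:
            raise ConfigError(
                "within_event_sd must be < between_event_gap_min / 6 "
                f"({self.within_event_sd!r} vs {self.between_event_gap_min!r})")
        bad = set(self.covariate_effects) - {"sex", "age", "immigrant"}
        if bad:
            raise ConfigError(f"covariate_effects has unknown keys {sorted(bad)}")
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")


@dataclass
class GMMParams:
    """Settings of the Gaussian-mixture event segmentation.

    ``max_components`` caps the per-site-day number of mixture components;
    the effective cap is ``min(max_components, ceil(n_detections / 3))``.
    Components with mixture weight below ``weight_prune_threshold``
    (default ``0.5 / n_detections``) are pruned after fitting.

    Mixture components are not events: BIC occasionally describes one
    burst with two heavily overlapping Gaussians. Adjacent components
    whose means are closer than ``merge_overlap_factor`` times the sum
    of their SDs are therefore combined into one event (0 disables).
    Bursts separated by quiet gaps are far outside this threshold.
    """

    max_components: int = 40
    weight_prune_threshold: float | None = None
    merge_overlap_factor: float = 2.0
    n_init: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_components <= 0:
            raise ConfigError("max_components must be a positive integer")
        if self.n_init <= 0:
            raise ConfigError("n_init must be a positive integer")
        if self.weight_prune_threshold is not None and not (
                0 <= self.weight_prune_threshold < 1):
            raise ConfigError("weight_prune_threshold must be in [0, 1)")
        if self.merge_overlap_factor < 0:
            raise ConfigError("merge_overlap_factor must be >= 0")


def _as_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    if "covariate_effects" in d:
        d["covariate_effects"] = dict(d["covariate_effects"])
    return d


def to_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_as_dict(obj), fh, sort_keys=True)


def sim_config_from_dict(d: Mapping) -> SimConfig:
    try:
        return SimConfig(**dict(d))
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
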