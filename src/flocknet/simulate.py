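"""Synthetic RFID feeder-visit streams with known ground truth.

The generator produces the data structures the downstream analysis
assumes: bursty flock visitation at feeders (tight Gaussian bursts of
antenna reads separated by quiet gaps), a latent per-bird sociality that
drives flock joining, and a configurable link from that sociality to
novel-food preference during experimental trials. Every stochastic step
is driven by a single seed, and the true event memberships and trait
values are returned alongside the stream for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig

__all__ = [
    "PeriodSpec",
    "default_period_specs",
    "generate_population",
    "simulate_period",
    "simulate_study",
    "write_fixtures",
    "read_detections",
    "read_traits",
]

#: Column order of the public detection stream.
STREAM_COLUMNS = [
    "tag_id", "site_id", "day", "time", "feeder_id", "food_type",
    "period", "feeder_position",
]

_DAWN_OFFSET_S = 6 * 3600  # recording starts pre-dawn; times are s since 06:00


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class PeriodSpec:
    """One recording period: its name, span, and feeder configuration."""

    name: str           # 'baseline' | 'trial1' | 'trial2'
    n_days: int
    day_offset: int     # first absolute day index of the period
    has_novel: bool     # trials pair a novel feeder with the familiar one
    green_sites: tuple = ()   # site ids whose novel food is green this period


def default_period_specs(config: SimConfig) -> list[PeriodSpec]:
    """Baseline then two trials; novel-food colours swap between trials.

    In trial 1 the first site gets red novel food and every other site
    green; trial 2 swaps the assignment.
    """
    sites = [f"S{i + 1}" for i in range(config.n_sites)]
    b, t = config.baseline_days, config.trial_days
    return [
        PeriodSpec("baseline", b, 0, False),
        PeriodSpec("trial1", t, b, True, tuple(sites[1:])),
        PeriodSpec("trial2", t, b + t, True, tuple(sites[:1])),
    ]


def generate_population(config: SimConfig) -> pd.DataFrame:
    """Draw the tagged population and its latent traits.

    Returns one row per bird: ``tag_id``, ``site_id``, ``sex`` (M/F),
    ``age`` (adult/juvenile), ``immigrant`` (bool), ``gregariousness``
    (latent sociality, Normal(0, sd)), ``detection_rate`` (lognormal
    per-bird read-rate multiplier, independent of sociality), and
    ``adventurousness`` — the bird's fixed contribution to the novel-use
    logit (``diet_slope_sociality * gregariousness`` plus trait effects).
    """
    if not isinstance(config, SimConfig):
        raise ConfigError("config must be a SimConfig")
    rng = np.random.default_rng([config.seed, 0])
    n, s = config.n_individuals_per_site, config.n_sites
    total = n * s
    site = np.repeat([f"S{i + 1}" for i in range(s)], n)
    tag = [f"{site[i]}-{i % n:03d}" for i in range(total)]
    sex = np.where(rng.random(total) < 0.5, "M", "F")
    age = np.where(rng.random(total) < 0.5, "adult", "juvenile")
    immigrant = rng.random(total) < 0.5
    greg = rng.normal(0.0, config.gregariousness_sd, total)
    det_rate = np.exp(rng.normal(0.0, config.detection_rate_sd, total))
    eff = config.covariate_effects
    adventurousness = (
        config.diet_slope_sociality * greg
        + eff.get("sex", 0.0) * (sex == "M")
        + eff.get("age", 0.0) * (age == "juvenile")
        + eff.get("immigrant", 0.0) * immigrant
    )
    return pd.DataFrame({
        "tag_id": tag, "site_id": site, "sex": sex, "age": age,
        "immigrant": immigrant, "gregariousness": greg,
        "detection_rate": det_rate, "adventurousness": adventurousness,
    })


def simulate_period(population: pd.DataFrame, config: SimConfig,
                    period: PeriodSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one recording period at every site.

    Per site-day the number of flocking events is Poisson; event centres
    are uniform over the foraging day subject to a minimum gap. Each
    local bird joins each event independently with probability
    ``logistic(join_intercept + join_slope * gregariousness)``; members
    emit ``Poisson(detections_per_member) + 1`` reads at
    ``Normal(centre, within_event_sd)``. During trials each read is
    assigned to the novel feeder with the bird's novel-use probability;
    the chronologically first read of each bird in the trial is instead
    assigned with the first-arrival (neophobia) probability, which by
    default carries no sociality effect.

    Returns
    -------
    stream : DataFrame
        Detection records (:data:`STREAM_COLUMNS` plus ``true_event_id``).
    truth_events : DataFrame
        One row per realized event: ``event_id``, ``site_id``, ``day``,
        ``centre_time``, ``member_ids`` (semicolon-joined).
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    rng = np.random.default_rng(
        [config.seed, 1, {"baseline": 0, "trial1": 1, "trial2": 2}[period.name]])
    L, gap = config.day_length_s, config.between_event_gap_min
    capacity = int(L // gap) + 1

    frames = []
    truth_rows = []
    event_counter = 0
    for site, pop in population.groupby("site_id", sort=True):
        greg = pop["gregariousness"].to_numpy()
        tags = pop["tag_id"].to_numpy()
        rate = (pop["detection_rate"].to_numpy()
                if "detection_rate" in pop else np.ones(len(pop)))
        p_join = _sigmoid(config.join_intercept + config.join_slope * greg)
        for d in range(period.n_days):
            day = period.day_offset + d
            n_events = min(rng.poisson(config.events_per_site_day), capacity)
            if n_events == 0:
                continue
            slack = L - (n_events - 1) * gap
            centres = (np.sort(rng.uniform(0.0, slack, n_events))
                       + gap * np.arange(n_events))
            joined = rng.random((n_events, len(pop))) < p_join
            ev_idx, bird_idx = np.nonzero(joined)
            if ev_idx.size == 0:
                continue
            reads = rng.poisson(
                config.detections_per_member * rate[bird_idx]) + 1
            det_ev = np.repeat(ev_idx, reads)
            det_bird = np.repeat(bird_idx, reads)
            t = rng.normal(centres[det_ev], config.within_event_sd)
            t = np.clip(np.round(t, 3), 0.0, L)
            # stable global ids for the non-empty events of this site-day
            realized = np.unique(ev_idx)
            id_map = np.full(n_events, -1)
            id_map[realized] = event_counter + np.arange(realized.size)
            frames.append(pd.DataFrame({
                "tag_id": tags[det_bird],
                "site_id": site,
                "day": day,
                "time": t,
                "true_event_id": id_map[det_ev],
            }))
            for e in realized:
                truth_rows.append((
                    id_map[e], site, day, centres[e],
                    ";".join(sorted(tags[bird_idx[ev_idx == e]])),
                ))
            event_counter += realized.size

    if not frames:
        stream = pd.DataFrame(
            columns=STREAM_COLUMNS + ["true_event_id"])
    else:
        stream = pd.concat(frames, ignore_index=True)
        stream = stream.sort_values(
            ["day", "site_id", "time", "tag_id"], kind="mergesort",
            ignore_index=True)
        stream["period"] = period.name
        stream = _assign_feeders(stream, population, config, period, rng)
        stream = stream[STREAM_COLUMNS + ["true_event_id"]]

    truth = pd.DataFrame(
        truth_rows,
        columns=["event_id", "site_id", "day", "centre_time", "member_ids"])
    truth["period"] = period.name
    return stream, truth


def _assign_feeders(stream, population, config, period, rng):
    """Attach feeder identity, food type and daily feeder position."""
    pop = population.set_index("tag_id")
    if not period.has_novel:
        stream["feeder_id"] = stream["site_id"] + ":base"
        stream["food_type"] = "baseline"
        stream["feeder_position"] = "centre"
        return stream

    green = stream["site_id"].isin(period.green_sites).to_numpy()
    adv = pop.loc[stream["tag_id"], "adventurousness"].to_numpy()
    p_novel = _sigmoid(config.diet_intercept + adv
                       + config.site_colour_effect * green)
    novel = rng.random(len(stream)) < p_novel

    # first-arrival choice: redrawn with the neophobia logit, which has no
    # sociality term unless configured
    first_idx = stream.groupby("tag_id", sort=True).head(1).index.to_numpy()
    greg = pop.loc[stream.loc[first_idx, "tag_id"], "gregariousness"].to_numpy()
    p_first = _sigmoid(
        config.diet_intercept
        + config.neophobia_slope_sociality * greg
        + config.site_colour_effect * green[first_idx])
    novel[first_idx] = rng.random(first_idx.size) < p_first

    stream["food_type"] = np.where(novel, "novel", "familiar")
    stream["feeder_id"] = stream["site_id"] + ":" + stream["food_type"]
    # feeders swap physical positions every other day (nuisance control;
    # no behavioural effect is simulated)
    left_is_novel = (stream["day"] % 2) == 0
    stream["feeder_position"] = np.where(
        left_is_novel == novel, "left", "right")
    return stream


def simulate_study(config: SimConfig):
    """Run all three periods; returns (population, stream, truth_events)."""
    population = generate_population(config)
    streams, truths = [], []
    offset = 0
    for spec in default_period_specs(config):
        s, t = simulate_period(population, config, spec)
        t["event_id"] += offset
        s["true_event_id"] += offset
        offset += len(t)
        streams.append(s)
        truths.append(t)
    stream = pd.concat(streams, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    return population, stream, truth


# ---------------------------------------------------------------------------
# fixture I/O


def _timestamps(stream: pd.DataFrame, start_date: str) -> pd.Series:
    base = pd.Timestamp(start_date)
    return (base
            + pd.to_timedelta(stream["day"], unit="D")
            + pd.to_timedelta(_DAWN_OFFSET_S + stream["time"], unit="s"))


def write_fixtures(stream: pd.DataFrame, truth_events: pd.DataFrame,
                   population: pd.DataFrame, directory,
                   start_date: str = "2018-01-11") -> dict[str, Path]:
    """Write the CSV file set: public data plus ground truth.

    ``detections.csv`` and ``traits.csv`` are the analysis inputs;
    ``truth_events.csv`` and ``truth_individuals.csv`` carry the ground
    truth used only by recovery tests.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    det = stream.loc[:, [c for c in STREAM_COLUMNS if c not in ("day", "time")]].copy()
    det.insert(1, "timestamp",
               _timestamps(stream, start_date).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
               if len(stream) else pd.Series(dtype=str))
    paths["detections"] = directory / "detections.csv"
    det.to_csv(paths["detections"], index=False)

    paths["traits"] = directory / "traits.csv"
    population[["tag_id", "site_id", "sex", "age", "immigrant"]].to_csv(
        paths["traits"], index=False)

    paths["truth_events"] = directory / "truth_events.csv"
    truth_events.to_csv(paths["truth_events"], index=False)

    paths["truth_individuals"] = directory / "truth_individuals.csv"
    population.to_csv(paths["truth_individuals"], index=False)
    return paths


def read_detections(path, start_date: str = "2018-01-11") -> pd.DataFrame:
    """Read a detection CSV back into the canonical stream frame.

    Reconstructs ``day`` (index from the study start date) and ``time``
    (seconds since 06:00 dawn) from the ISO timestamps.
    """
    df = pd.read_csv(path, dtype={"tag_id": str, "site_id": str})
    ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    base = pd.Timestamp(start_date)
    df["day"] = (ts.dt.normalize() - base).dt.days
    df["time"] = ((ts - ts.dt.normalize()).dt.total_seconds()
                  - _DAWN_OFFSET_S).round(3)
    return df[STREAM_COLUMNS]


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tag_id": str, "site_id": str})
    df["immigrant"] = df["immigrant"].astype(bool)
    return df
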