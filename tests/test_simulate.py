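"""Generator contracts: determinism, trait distributions, effect wiring."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from pandas.testing import assert_frame_equal
from scipy import stats

from flocknet.config import ConfigError, SimConfig
from flocknet.simulate import (default_period_specs, generate_population,
                               read_detections, read_traits, simulate_period,
                               simulate_study, write_fixtures)


def test_population_counts_and_determinism():
    cfg = SimConfig(n_individuals_per_site=20, n_sites=2, seed=7)
    pop = generate_population(cfg)
    assert len(pop) == 40
    assert (pop.groupby("site_id").size() == 20).all()
    assert pop["tag_id"].is_unique
    assert_frame_equal(pop, generate_population(cfg))


def test_gregariousness_distribution():
    """Sample SD of the latent sociality matches its configured value."""
    cfg = SimConfig(n_individuals_per_site=5000, n_sites=2,
                    gregariousness_sd=1.0, seed=3)
    pop = generate_population(cfg)
    assert abs(pop["gregariousness"].std() - 1.0) < 0.03
    assert abs(pop["gregariousness"].mean()) < 0.05


@pytest.mark.parametrize("field, value", [
    ("n_individuals_per_site", 0),
    ("n_sites", -1),
    ("baseline_days", 0),
    ("events_per_site_day", 0.0),
    ("within_event_sd", 100.0),   # violates the burst-separability bound
    ("detection_rate_sd", -0.5),
])
def test_invalid_config_names_offending_field(field, value):
    with pytest.raises(ConfigError, match=field.split("_")[0]):
        SimConfig(**{field: value})


def test_unknown_covariate_key_rejected():
    with pytest.raises(ConfigError, match="covariate_effects"):
        SimConfig(covariate_effects={"wingspan": 1.0})


def test_empty_population_rejected():
    cfg = SimConfig(seed=0)
    with pytest.raises(ValueError, match="empty"):
        simulate_period(generate_population(cfg).iloc[:0], cfg,
                        default_period_specs(cfg)[0])


def test_null_slopes_decouple_sociality_from_novel_use():
    """With both slopes at 0, gregariousness predicts nothing."""
    cfg = SimConfig(n_individuals_per_site=100, join_slope=0.0,
                    diet_slope_sociality=0.0, baseline_days=1, trial_days=5,
                    seed=11)
    pop, stream, _ = simulate_study(cfg)
    tr = stream[stream["period"] == "trial1"]
    prop = (tr["food_type"] == "novel").groupby(tr["tag_id"]).mean()
    df = pop.set_index("tag_id").loc[prop.index]
    r = stats.pearsonr(df["gregariousness"], prop)[0]
    assert abs(r) < 0.05


def test_reads_cluster_around_their_event_centre():
    """Tight bursts: every read within 5 SD of exactly its own centre."""
    cfg = SimConfig(n_individuals_per_site=30, within_event_sd=2.0,
                    between_event_gap_min=600.0, baseline_days=2, seed=5)
    pop, stream, truth = simulate_study(cfg)
    base = stream[stream["period"] == "baseline"]
    centres = truth.set_index("event_id")["centre_time"]
    dist_own = (base["time"] - base["true_event_id"].map(centres)).abs()
    assert (dist_own <= 5 * 2.0 + 1e-9).all()
    # and no other centre of the same site-day is closer than its own
    for (site, day), g in base.groupby(["site_id", "day"]):
        cs = truth[(truth["site_id"] == site)
                   & (truth["day"] == day)]["centre_time"].to_numpy()
        nearest = cs[np.argmin(
            np.abs(g["time"].to_numpy()[:, None] - cs), axis=1)]
        own = g["true_event_id"].map(centres).to_numpy()
        assert np.allclose(nearest, own)


def test_positive_diet_slope_orders_gregariousness_quartiles():
    cfg = SimConfig(n_individuals_per_site=100, diet_slope_sociality=0.5,
                    baseline_days=1, trial_days=4, seed=13)
    pop, stream, _ = simulate_study(cfg)
    tr = stream[stream["period"] == "trial1"]
    prop = (tr["food_type"] == "novel").groupby(tr["tag_id"]).mean()
    greg = pop.set_index("tag_id").loc[prop.index, "gregariousness"]
    q = pd.qcut(greg, 4, labels=False)
    assert prop[q == 3].mean() > prop[q == 0].mean()


def test_oracle_logistic_recovers_diet_slope():
    """An oracle logit of novel counts on true gregariousness recovers
    the generative slope to +/-0.1 at large n."""
    cfg = SimConfig(n_individuals_per_site=250, diet_slope_sociality=0.5,
                    baseline_days=1, seed=17)
    pop, stream, _ = simulate_study(cfg)
    tr = stream[stream["period"] == "trial1"]
    counts = pd.crosstab(tr["tag_id"], tr["food_type"])
    df = pop.set_index("tag_id").loc[counts.index]
    x = np.column_stack([np.ones(len(df)), df["gregariousness"],
                         (df["site_id"] != "S1").astype(float)])
    res = sm.GLM(counts[["novel", "familiar"]].to_numpy(), x,
                 family=sm.families.Binomial()).fit()
    assert abs(res.params[1] - 0.5) < 0.1


def test_group_sizes_match_join_probability_model():
    """Realized event sizes follow the Poisson-binomial implied by the
    per-bird join probabilities (chi-square GOF, Bonferroni over
    replicates)."""
    n_rep, alpha = 20, 0.01
    rejected = 0
    for rep in range(n_rep):
        cfg = SimConfig(n_individuals_per_site=30, n_sites=1,
                        baseline_days=6, trial_days=1, seed=1000 + rep)
        pop, _, truth = simulate_study(cfg)
        p = 1 / (1 + np.exp(-(cfg.join_intercept
                              + cfg.join_slope * pop["gregariousness"])))
        # Poisson-binomial pmf by dynamic programming
        pmf = np.array([1.0])
        for pi in p:
            pmf = np.convolve(pmf, [1 - pi, pi])
        sizes = truth[truth["period"] == "baseline"]["member_ids"].str.count(";") + 1
        # observed sizes exclude empty events -> condition the pmf on n>0
        pmf = pmf[1:] / pmf[1:].sum()
        obs = np.bincount(sizes, minlength=len(pmf) + 1)[1:]
        exp = pmf * obs.sum()
        # merge low-expectation bins from the right
        cut = np.searchsorted(np.cumsum(exp[::-1]), 5.0)
        k = len(exp) - cut
        obs_b = np.append(obs[:k], obs[k:].sum())
        exp_b = np.append(exp[:k], exp[k:].sum())
        stat = ((obs_b - exp_b) ** 2 / exp_b).sum()
        pval = stats.chi2.sf(stat, len(obs_b) - 1)
        rejected += pval < alpha / n_rep
    assert rejected == 0


def test_fixture_roundtrip(tmp_path, small_study):
    cfg, population, stream, truth = small_study
    paths = write_fixtures(stream, truth, population, tmp_path)
    back = read_detections(paths["detections"])
    cols = ["tag_id", "site_id", "day", "time", "feeder_id", "food_type",
            "period", "feeder_position"]
    pd.testing.assert_frame_equal(back[cols],
                                  stream[cols].reset_index(drop=True))
    tr = read_traits(paths["traits"])
    assert list(tr["tag_id"]) == list(population["tag_id"])
    assert len(pd.read_csv(paths["truth_events"])) == len(truth)


def test_fixture_determinism_bytes(tmp_path, small_study):
    cfg, *_ = small_study
    a, b = tmp_path / "a", tmp_path / "b"
    for d in (a, b):
        pop, stream, truth = simulate_study(cfg)
        write_fixtures(stream, truth, pop, d)
    for name in ("detections.csv", "traits.csv", "truth_events.csv"):
        assert (a / name).read_bytes() == (b / name).read_bytes()


def test_empty_stream_writes_header_only(tmp_path):
    import flocknet.simulate as simmod
    stream = pd.DataFrame(columns=simmod.STREAM_COLUMNS + ["true_event_id"])
    truth = pd.DataFrame(columns=["event_id", "site_id", "day",
                                  "centre_time", "member_ids", "period"])
    pop = generate_population(SimConfig(n_individuals_per_site=2, seed=0))
    paths = write_fixtures(stream, truth, pop, tmp_path)
    assert len(pd.read_csv(paths["detections"])) == 0
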