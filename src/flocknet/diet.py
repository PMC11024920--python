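"""Dietary-decision response variables and GLMs.

The central model treats each bird's trial-period feeder records as a
binomial response — detections on the novel-food feeder are "successes",
detections on the familiar-food feeder "fails" — so that both the
direction and the confidence of a bird's preference enter the response.
Binomial counts from feeder streams are overdispersed, so the models use
a quasi-binomial error structure: coefficients equal the binomial-logit
fit, standard errors are inflated by the square root of the Pearson
dispersion, and Wald tests use a t reference on the residual degrees of
freedom. Latency (neophobia) responses use Gaussian models instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "FitResult", "build_responses", "fit_glm",
           "prior_detection_covariate", "build_design"]

RESPONSE_KINDS = ("usage", "neophobia_arrival", "latency_clock",
                  "latency_elapsed", "post_first_usage")
CENTRALITY_METRICS = ("strength", "average_edge_weight",
                      "eigenvector_centrality", "mean_flock_size",
                      "n_unique_associates")
DEFAULT_COVARIATES = ("site", "sex", "age", "immigrant", "prior_detections")

_DAWN_OFFSET_S = 6 * 3600


@dataclass(frozen=True)
class ModelSpec:
    """One model: a response kind, a focal centrality metric, covariates.

    The error family is forced by the response: binomial counts and
    binary responses are quasi-binomial with logit link; latencies are
    Gaussian. ``standardize`` optionally z-scores the continuous
    predictors for cross-metric comparison (coefficients are reported on
    the raw scale by default). ``log_prior`` applies log1p to the
    prior-detections covariate.
    """

    response: str = "usage"
    metric: str = "strength"
    covariates: tuple = DEFAULT_COVARIATES
    standardize: bool = False
    log_prior: bool = False

    def __post_init__(self) -> None:
        if self.response not in RESPONSE_KINDS:
            raise ValueError(f"unknown response kind {self.response!r}")
        if self.metric not in CENTRALITY_METRICS:
            raise ValueError(f"unknown centrality metric {self.metric!r}")

    @property
    def family(self) -> str:
        return ("gaussian" if self.response.startswith("latency")
                else "quasibinomial")

    @property
    def name(self) -> str:
        return f"{self.response}~{self.metric}"


@dataclass
class FitResult:
    """GLM fit summary: one row per term plus model-level diagnostics."""

    table: pd.DataFrame          # term, coef, se, t, p
    phi: float                   # Pearson dispersion chi2 / (n - p)
    n_obs: int
    df_resid: int
    converged: bool
    family: str
    n_dropped: int = 0
    spec: ModelSpec | None = None
    design: pd.DataFrame | None = field(default=None, repr=False)
    endog: np.ndarray | None = field(default=None, repr=False)

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "coef"])


def build_responses(trial_stream: pd.DataFrame,
                    day_length_s: float = 28_800.0) -> pd.DataFrame:
    """Per-bird trial responses from one trial's detection stream.

    For every bird detected during the trial: novel and familiar
    detection counts; whether the chronologically first record of the
    trial was at the novel feeder; the clock-time latency (seconds since
    midnight of the first-use day) and elapsed foraging-time latency
    (within-day spans only — nights are not foraging time) to first
    novel-feeder use; and novel/familiar counts strictly after that
    first use. Latencies are missing for birds never recorded at the
    novel feeder; their post-first counts are 0.
    """
    bad = set(trial_stream["food_type"].unique()) - {"novel", "familiar"}
    if bad:
        raise ValueError(
            f"trial stream has records without a novel/familiar food_type: {sorted(bad)}")
    s = trial_stream.sort_values(["day", "time"], kind="mergesort")
    s = s.reset_index(drop=True)
    s["_novel"] = s["food_type"] == "novel"
    s["_pos"] = s.groupby("tag_id", sort=True).cumcount()
    day0 = int(s["day"].min()) if len(s) else 0

    grp = s.groupby("tag_id", sort=True)
    n_det = grp.size()
    novel_count = grp["_novel"].sum().astype(int)
    familiar_count = (n_det - novel_count).astype(int)
    first = grp[["day", "time", "_novel"]].first()

    # first novel-feeder record per bird, where one exists
    fn = s[s["_novel"]].groupby("tag_id", sort=True)[["day", "time", "_pos"]].first()
    out = pd.DataFrame({
        "novel_count": novel_count,
        "familiar_count": familiar_count,
        "first_arrival_novel": first["_novel"],
        "n_detections": n_det,
    })
    out["latency_clock"] = _DAWN_OFFSET_S + fn["time"]
    same_day = fn["day"] == first.loc[fn.index, "day"]
    elapsed = ((day_length_s - first.loc[fn.index, "time"])
               + (fn["day"] - first.loc[fn.index, "day"] - 1) * day_length_s
               + fn["time"])
    elapsed[same_day] = (fn["time"] - first.loc[fn.index, "time"])[same_day]
    out["latency_elapsed"] = elapsed
    # every other novel record falls strictly after the first; records
    # before the first novel one are all familiar
    out["post_first_novel_count"] = (novel_count - 1).clip(lower=0).where(
        novel_count > 0, 0)
    out["post_first_familiar_count"] = (familiar_count - fn["_pos"]).reindex(
        out.index).fillna(0).astype(int)
    out["first_use_day"] = (fn["day"] - day0).reindex(out.index).fillna(-1).astype(int)
    out.index.name = "tag_id"
    return out[["novel_count", "familiar_count", "first_arrival_novel",
                "latency_clock", "latency_elapsed", "post_first_novel_count",
                "post_first_familiar_count", "first_use_day", "n_detections"]]


def prior_detection_covariate(prior_stream: pd.DataFrame) -> pd.Series:
    """Raw feeder-detection count per bird in the pre-trial period."""
    counts = prior_stream.groupby("tag_id").size()
    counts.name = "prior_detections"
    return counts


def build_design(responses: pd.DataFrame, metrics: pd.DataFrame,
                 traits: pd.DataFrame, spec: ModelSpec):
    """Merge tables and assemble (endog, design) for the requested model.

    Birds missing the focal metric or any covariate (e.g. absent from the
    prior-period network, or isolated when the metric is average edge
    weight) are dropped; the count is logged and returned.
    Returns ``(endog, X, n_dropped)`` where endog is an (n, 2)
    successes/fails array for binomial-family responses or an (n,) vector
    for Gaussian ones, and X is the design DataFrame (intercept first).
    """
    df = responses.join(metrics, how="inner", rsuffix="_prior").join(
        traits.set_index("tag_id"), how="left")

    if spec.response == "usage":
        endog_cols = ["novel_count", "familiar_count"]
    elif spec.response == "post_first_usage":
        endog_cols = ["post_first_novel_count", "post_first_familiar_count"]
    elif spec.response == "neophobia_arrival":
        df["_success"] = df["first_arrival_novel"].astype(int)
        df["_fail"] = 1 - df["_success"]
        endog_cols = ["_success", "_fail"]
    else:
        endog_cols = [spec.response]

    x = pd.DataFrame(index=df.index)
    x["intercept"] = 1.0
    x[spec.metric] = df[spec.metric]
    for cov in spec.covariates:
        if cov == "site":
            sites = sorted(df["site_id"].dropna().unique())
            for s in sites[1:]:
                x[f"site[{s}]"] = (df["site_id"] == s).astype(float)
        elif cov == "sex":
            x["sex[M]"] = (df["sex"] == "M").astype(float)
        elif cov == "age":
            x["age[juvenile]"] = (df["age"] == "juvenile").astype(float)
        elif cov == "immigrant":
            x["immigrant"] = df["immigrant"].astype(float)
        elif cov == "prior_detections":
            v = df["prior_detections"].astype(float)
            x["prior_detections"] = np.log1p(v) if spec.log_prior else v
        else:
            x[cov] = df[cov].astype(float)

    keep = x.notna().all(axis=1) & df[endog_cols].notna().all(axis=1)
    if spec.response in ("usage", "post_first_usage"):
        keep &= df[endog_cols].sum(axis=1) > 0   # birds with no trials carry no information
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d of %d birds with incomplete data for %s",
                    n_dropped, len(df), spec.name)
    df, x = df[keep], x[keep]

    if spec.standardize:
        for col in x.columns:
            if col == "intercept":
                continue
            sd = x[col].std(ddof=0)
            if sd > 0:
                x[col] = (x[col] - x[col].mean()) / sd

    if spec.family == "quasibinomial":
        endog = df[endog_cols].to_numpy(dtype=float)
    else:
        endog = df[endog_cols[0]].to_numpy(dtype=float)
    return endog, x, n_dropped


def fit_glm(responses: pd.DataFrame, metrics: pd.DataFrame,
            traits: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the requested GLM.

    Quasi-binomial responses: binomial-logit fit by IRLS; the Pearson
    dispersion ``phi = chi2_pearson / (n - p)`` rescales the standard
    errors (coefficients are identical to the plain binomial fit) and
    Wald t statistics are referred to a t distribution on ``n - p``
    degrees of freedom. Gaussian responses: ordinary least squares.
    Non-convergence and (quasi-)separation are flagged on the result
    rather than raised.
    """
    endog, x, n_dropped = build_design(responses, metrics, traits, spec)
    n, p = x.shape
    if n < p + 5:
        raise ValueError(
            f"{spec.name}: {n} observations for {p} parameters (need >= p + 5)")
    xv = x.to_numpy(dtype=float)
    if spec.family == "quasibinomial":
        model = sm.GLM(endog, xv, family=sm.families.Binomial())
        res = model.fit(maxiter=50, tol=1e-10)
        phi = float(res.pearson_chi2 / res.df_resid)
        se = res.bse * np.sqrt(phi)
        converged = bool(res.converged) and np.isfinite(res.params).all() \
            and np.max(np.abs(res.params)) < 1e4
    else:
        model = sm.OLS(endog, xv)
        res = model.fit()
        phi = float(res.scale)
        se = res.bse
        converged = np.isfinite(res.params).all()
    coef = res.params
    df_resid = int(res.df_resid)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef / se
    pvals = 2 * stats.t.sf(np.abs(t), df_resid)
    table = pd.DataFrame({"term": x.columns, "coef": coef, "se": se,
                          "t": t, "p": pvals})
    return FitResult(table=table, phi=phi, n_obs=n, df_resid=df_resid,
                     converged=converged, family=spec.family,
                     n_dropped=n_dropped, spec=spec, design=x, endog=endog)
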