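"""Stratified node-attribute permutation tests for model coefficients.

Network-derived predictors violate the independence assumptions behind
asymptotic GLM p-values, so each model term is additionally tested
against a null distribution built by permutation: the response variable
is reassigned among individuals within the same site and period (space
and time strata), the model is refitted with everything else unchanged
— the predictor matrix, and hence the exact distributions of and
covariances between the predictors, is untouched — and the coefficient
of every term is recorded. ``p_rand`` is the two-tailed position of the
observed coefficient in its null distribution, with an add-one
correction so it can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diet import FitResult, ModelSpec, build_design, fit_glm
from .irls import batched_logit_irls, batched_ols

__all__ = ["PermutationPlan", "PermutationResult", "PermutationError",
           "permute_within_strata", "permutation_test"]


class PermutationError(RuntimeError):
    """Raised when too many permutation refits fail to converge."""


@dataclass
class PermutationPlan:
    """How to build the null: number of draws, strata, seed.

    ``strata`` maps individual id -> stratum label (site, or site-period);
    responses are only ever exchanged within a stratum.
    """

    n_permutations: int = 10_000
    seed: int = 0
    strata: pd.Series | None = None
    max_redraw_fraction: float = 0.01


@dataclass
class PermutationResult:
    """Observed coefficients, their permutation p-values, and the nulls."""

    table: pd.DataFrame                      # term, coef, p_rand
    null_distributions: pd.DataFrame         # (n_permutations, terms)
    n_permutations: int
    n_redrawn: int
    observed: FitResult

    def p_rand(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p_rand"])


def permute_within_strata(values, strata: pd.Series,
                          rng: np.random.Generator):
    """Shuffle values among individuals within each stratum.

    ``values`` may be a Series or a DataFrame — a DataFrame's rows move
    as a unit, which is how a (novel_count, familiar_count) pair travels
    together. The index is preserved; within each stratum the multiset
    of values is preserved exactly; nothing crosses strata.
    """
    strata = strata.reindex(values.index)
    if strata.isna().any():
        missing = list(values.index[strata.isna()])[:5]
        raise ValueError(f"individuals missing a stratum: {missing}")
    taker = np.arange(len(values))
    codes = pd.factorize(strata)[0]
    for s in np.unique(codes):
        pos = np.flatnonzero(codes == s)
        taker[pos] = pos[rng.permutation(pos.size)]
    out = values.iloc[taker].copy()
    out.index = values.index
    return out


def _strata_codes(index: pd.Index, strata: pd.Series | None) -> np.ndarray:
    if strata is None:
        return np.zeros(len(index), dtype=int)
    s = strata.reindex(index)
    if s.isna().any():
        missing = list(index[s.isna()])[:5]
        raise ValueError(f"individuals missing a stratum: {missing}")
    return pd.factorize(s)[0]


def _permutation_matrix(n: int, codes: np.ndarray, b: int,
                        rng: np.random.Generator) -> np.ndarray:
    """(n, b) array of row-index permutations respecting the strata."""
    take = np.tile(np.arange(n)[:, None], (1, b))
    for s in np.unique(codes):
        pos = np.flatnonzero(codes == s)
        order = np.argsort(rng.random((pos.size, b)), axis=0)
        take[pos] = pos[order]
    return take


def permutation_test(responses: pd.DataFrame, metrics: pd.DataFrame,
                     traits: pd.DataFrame, spec: ModelSpec,
                     plan: PermutationPlan) -> PermutationResult:
    """Null distribution and p_rand for every term of one model.

    The observed fit must converge. Each permutation reassigns the
    response within strata and refits; for binomial-family responses the
    (successes, fails) pair moves as a unit. A permuted refit that drifts
    to extreme coefficients — (quasi-)separation, where the likelihood
    maximum is at infinity — is retained: its statistic belongs in the
    far tail of the null, and discarding such draws would narrow the
    null and inflate the type-I error. Only numerically failed refits
    (non-finite estimates) are redrawn with fresh permutations, capped
    at ``plan.max_redraw_fraction`` of the requested draws — beyond the
    cap the test aborts rather than report a biased null.

    ``p_rand = (1 + #{|coef_b| >= |coef_obs|}) / (B + 1)`` per term.
    """
    observed = fit_glm(responses, metrics, traits, spec)
    if not observed.converged:
        raise PermutationError(f"observed fit for {spec.name} did not converge")
    x = observed.design.to_numpy(dtype=float)
    endog = observed.endog
    n = x.shape[0]
    codes = _strata_codes(observed.design.index, plan.strata)
    beta_obs = observed.table["coef"].to_numpy()

    b_total = plan.n_permutations
    max_redraws = int(np.ceil(plan.max_redraw_fraction * b_total))
    rng = np.random.default_rng([plan.seed, 99])

    nulls = np.empty((b_total, x.shape[1]))
    filled = 0
    n_redrawn = 0
    while filled < b_total:
        b = b_total - filled
        take = _permutation_matrix(n, codes, b, rng)
        if observed.family == "quasibinomial":
            succ = endog[:, 0][take]
            tot = endog.sum(axis=1)[take]
            beta, ok, _ = batched_logit_irls(x, succ, tot, beta0=beta_obs)
        else:
            beta = batched_ols(x, endog[take])
            ok = np.isfinite(beta).all(axis=1)
        good = np.flatnonzero(ok)
        nulls[filled:filled + good.size] = beta[good]
        filled += good.size
        failed = b - good.size
        n_redrawn += failed
        if n_redrawn > max_redraws:
            raise PermutationError(
                f"{n_redrawn} non-convergent permutation refits for "
                f"{spec.name} (cap {max_redraws})")

    exceed = (np.abs(nulls) >= np.abs(beta_obs)[None, :]).sum(axis=0)
    p_rand = (1.0 + exceed) / (b_total + 1.0)
    terms = list(observed.design.columns)
    table = pd.DataFrame({"term": terms, "coef": beta_obs, "p_rand": p_rand})
    return PermutationResult(
        table=table,
        null_distributions=pd.DataFrame(nulls, columns=terms),
        n_permutations=b_total, n_redrawn=n_redrawn, observed=observed)
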