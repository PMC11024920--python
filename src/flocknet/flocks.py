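"""Flocking-event detection from bursty detection streams.

Birds foraging in fission-fusion flocks produce a temporal stream of
antenna reads made of dense bursts separated by quiet gaps. Each
site-day is segmented into flocking events by fitting one-dimensional
Gaussian mixtures over the detection times, choosing the number of
components by BIC, and assigning every detection to its
maximum-responsibility component. The events feed a binary
group-by-individual (GBI) matrix.
"""

from __future__ import annotations

import math
import zlib

import numpy as np
import pandas as pd

from .config import GMMParams

__all__ = ["segment_stream", "build_gbi", "typical_group_size",
           "TypicalGroupSize"]

EVENT_COLUMNS = ["event_id", "site_id", "day", "start_time", "end_time",
                 "n_members", "n_detections", "member_ids"]

# floor the component variance to keep EM away from point-mass collapse
# on coincident or near-coincident reads: a flock visit spans at least
# seconds, and sub-second repeat reads are collapsed upstream
_VAR_FLOOR = 1.0
_EM_TOL = 1e-7
_EM_MAX_ITER = 300
# BIC against K is U-shaped in practice; stop after this many K values
# without improvement
_BIC_PATIENCE = 8


def _em_1d(x: np.ndarray, w, means, var):
    """Run EM to convergence from the given start; returns (ll, params)."""
    n = x.size
    w, means, var = (np.asarray(a, dtype=float).copy()
                     for a in (w, means, var))
    dx2 = np.empty((n, w.size))
    prev_ll = -np.inf
    for _ in range(_EM_MAX_ITER):
        np.subtract(x[:, None], means, out=dx2)
        np.square(dx2, out=dx2)
        # unnormalized responsibilities; bursts are far apart so extreme
        # exponents underflow harmlessly to 0
        p = np.exp(dx2 / (-2.0 * var)) * (w / np.sqrt(2 * np.pi * var))
        tot = p.sum(axis=1)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.log(tot).sum())
        resp = p / tot[:, None]
        nk = np.maximum(resp.sum(axis=0), 1e-12)
        w = nk / n
        means = resp.T @ x / nk
        np.subtract(x[:, None], means, out=dx2)
        np.square(dx2, out=dx2)
        var = np.maximum((resp * dx2).sum(axis=0) / nk, _VAR_FLOOR)
        if ll - prev_ll < _EM_TOL * max(1.0, abs(ll)):
            break
        prev_ll = ll
    return ll, (w, means, var)


def _fit_gmm_1d(x: np.ndarray, k: int, rng: np.random.Generator,
                n_init: int):
    """Best-of-inits EM fit of a K-component mixture; returns (bic, params).

    The first initialization is deterministic: the sorted times are cut
    at the k-1 largest inter-detection gaps and each segment seeds one
    component with its mean, variance and mass. For bursty streams this
    start is near the optimum, so EM converges in a few iterations and
    the BIC curve over k is clean. Further restarts (``n_init > 1``)
    draw k distinct detection times as means.
    """
    n = x.size
    if k > n:
        return None
    span = max(float(x[-1] - x[0]), 1.0)

    starts = []
    cuts = np.sort(np.argsort(np.diff(x))[::-1][:k - 1] + 1) if k > 1 else []
    segments = np.split(x, cuts)
    starts.append((
        np.array([len(s) / n for s in segments]),
        np.array([s.mean() for s in segments]),
        np.array([max(s.var(), _VAR_FLOOR) for s in segments]),
    ))
    for _ in range(n_init - 1):
        starts.append((
            np.full(k, 1.0 / k),
            np.sort(rng.choice(x, size=k, replace=False)),
            np.full(k, max((span / (2.0 * k)) ** 2, _VAR_FLOOR)),
        ))
    best = None
    for w0, means0, var0 in starts:
        ll, gmm = _em_1d(x, w0, means0, var0)
        n_params = 3 * k - 1
        bic = -2.0 * ll + n_params * math.log(n)
        if best is None or bic < best[0]:
            best = (bic, gmm)
    return best


def _segment_day(x: np.ndarray, params: GMMParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Return a component label per detection time for one site-day."""
    n = x.size
    if n == 1:
        return np.zeros(1, dtype=int)
    sort_idx = np.argsort(x, kind="stable")
    x = x[sort_idx]  # EM is order-invariant; sorting helps quantile init
    k_max = max(min(params.max_components, math.ceil(n / 3)), 1)

    cache: dict[int, tuple] = {}

    def bic_at(k: int) -> float:
        if k not in cache:
            fit = _fit_gmm_1d(x, k, rng, params.n_init)
            cache[k] = fit if fit is not None else (np.inf, None)
        return cache[k][0]

    # BIC over K is U-shaped in practice: scan a coarse grid first, then
    # refine around the coarse minimum
    step = max(1, k_max // 10)
    coarse = list(range(1, k_max + 1, step))
    if coarse[-1] != k_max:
        coarse.append(k_max)
    best_k, since_best = coarse[0], 0
    for k in coarse:
        if bic_at(k) < bic_at(best_k):
            best_k, since_best = k, 0
        else:
            since_best += 1
            if since_best >= _BIC_PATIENCE:
                break
    for k in range(max(1, best_k - step + 1), min(k_max, best_k + step - 1) + 1):
        if bic_at(k) < bic_at(best_k):
            best_k = k
    w, means, var = cache[best_k][1]
    logp = (np.log(np.maximum(w, 1e-300)) - 0.5 * np.log(2 * np.pi * var)
            - 0.5 * (x[:, None] - means) ** 2 / var)
    labels = np.argmax(logp, axis=1)

    # prune near-empty components: reassign their detections to the
    # nearest surviving component mean
    threshold = (params.weight_prune_threshold
                 if params.weight_prune_threshold is not None else 0.5 / n)
    counts = np.bincount(labels, minlength=w.size)
    keep = (w >= threshold) & (counts > 0)
    if not keep.any():
        keep[np.argmax(counts)] = True
    if not keep.all():
        surviving = np.flatnonzero(keep)
        dead = ~keep[labels]
        nearest = surviving[np.argmin(
            np.abs(x[dead, None] - means[surviving]), axis=1)]
        labels[dead] = nearest

    # components are not events: combine adjacent components that
    # overlap heavily (two Gaussians describing one burst)
    if params.merge_overlap_factor > 0:
        surviving = np.unique(labels)
        order = surviving[np.argsort(means[surviving])]
        group = np.zeros(w.size, dtype=int)
        g = 0
        group[order[0]] = 0
        for prev, cur in zip(order[:-1], order[1:]):
            gap = means[cur] - means[prev]
            if gap >= params.merge_overlap_factor * (
                    np.sqrt(var[prev]) + np.sqrt(var[cur])):
                g += 1
            group[cur] = g
        labels = group[labels]

    out = np.empty(n, dtype=int)
    out[sort_idx] = labels
    return out


def segment_stream(stream: pd.DataFrame, params: GMMParams | None = None
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Segment a detection stream into flocking events.

    The stream is partitioned by site and day (no event spans a day
    boundary) and each partition's detection times are clustered with a
    BIC-selected Gaussian mixture. Detections at different feeders of the
    same site are pooled: the paired trial feeders sit within a metre of
    each other, so their visits belong to the same flock visit.

    Returns
    -------
    events : DataFrame
        One row per event (:data:`EVENT_COLUMNS`), sorted by site, day
        and start time, with sequential ``event_id``.
    assignment : Series
        Event id per detection, aligned with ``stream``'s index. Together
        the events partition the stream: every detection belongs to
        exactly one event.
    """
    if params is None:
        params = GMMParams()
    assignment = pd.Series(-1, index=stream.index, dtype=int, name="event_id")
    rows = []
    eid = 0
    if len(stream):
        for (site, day), grp in stream.groupby(["site_id", "day"], sort=True):
            rng = np.random.default_rng(
                [params.seed, zlib.crc32(f"{site}|{day}".encode())])
            t = grp["time"].to_numpy(dtype=float)
            labels = _segment_day(t, params, rng)
            # order events by their first detection time
            order = pd.Series(t).groupby(labels).min().sort_values()
            for lab in order.index:
                mask = labels == lab
                idx = grp.index[mask]
                assignment.loc[idx] = eid
                members = sorted(set(grp.loc[idx, "tag_id"]))
                rows.append((eid, site, day, t[mask].min(), t[mask].max(),
                             len(members), int(mask.sum()),
                             ";".join(members)))
                eid += 1
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return events, assignment


def build_gbi(events: pd.DataFrame, individual_universe=None,
              include_unobserved: bool = False) -> pd.DataFrame:
    """Binary group-by-individual matrix: rows events, columns birds.

    Birds listed in ``individual_universe`` but never observed appear as
    all-zero columns only when ``include_unobserved`` is set; otherwise
    the columns are exactly the union of event members.
    """
    if events["event_id"].duplicated().any():
        raise ValueError("duplicate event ids")
    observed = sorted({m for s in events["member_ids"]
                       for m in str(s).split(";") if m})
    if include_unobserved and individual_universe is not None:
        cols = sorted(set(observed) | set(individual_universe))
    else:
        cols = observed
    gbi = pd.DataFrame(0, index=events["event_id"].to_numpy(), columns=cols,
                       dtype=np.int8)
    col_pos = {c: i for i, c in enumerate(cols)}
    vals = gbi.to_numpy()
    for row, members in enumerate(events["member_ids"]):
        for m in str(members).split(";"):
            if m:
                vals[row, col_pos[m]] = 1
    gbi.index.name = "event_id"
    return gbi


class TypicalGroupSize(float):
    """Size-weighted mean group size with its standard error."""

    se: float

    def __new__(cls, value: float, se: float):
        obj = super().__new__(cls, value)
        obj.se = se
        return obj


def typical_group_size(events: pd.DataFrame) -> TypicalGroupSize:
    """Group size experienced by the average individual.

    For event sizes ``n_i`` this is ``sum(n_i^2) / sum(n_i)``: each event
    is counted once per member, so large flocks weigh in proportion to
    how many birds experienced them. The standard error is that of the
    membership-weighted sample (each of the ``sum(n_i)`` individual
    memberships contributes its event's size).
    """
    if len(events) == 0:
        raise ValueError("typical group size undefined for an empty event list")
    n = events["n_members"].to_numpy(dtype=float)
    total = n.sum()
    value = float((n ** 2).sum() / total)
    # variance of event size over the membership-expanded sample
    var = float((n * (n - value) ** 2).sum() / total)
    se = math.sqrt(var / total)
    return TypicalGroupSize(value, se)
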