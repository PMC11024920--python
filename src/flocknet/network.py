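"""SRI-weighted social networks and node centrality metrics.

Dyadic association is measured with the Simple Ratio Index: the
proportion of flocking events involving either bird of a dyad in which
both were seen together, ``SRI(A,B) = F_AB / (F_A + F_B - F_AB)`` where
``F_A`` counts the events containing A. The resulting network is
symmetric and weighted, with edge weights in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

__all__ = ["SocialNetwork", "sri_network", "network_density", "node_metrics",
           "write_edge_list"]


@dataclass
class SocialNetwork:
    """Symmetric weighted association matrix plus node labels."""

    node_ids: list
    weights: np.ndarray          # (N, N), symmetric, zero diagonal
    period: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.node_ids), len(self.node_ids)):
            raise ValueError("weight matrix shape does not match node ids")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.size and (w.min() < 0 or w.max() > 1):
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_ids,
                            columns=self.node_ids)


def sri_network(gbi: pd.DataFrame, period: str | None = None) -> SocialNetwork:
    """Simple-Ratio-Index network from a binary group-by-individual matrix.

    Dyads in which neither bird was ever seen get weight 0.
    """
    x = gbi.to_numpy()
    if x.size and not np.isin(x, (0, 1)).all():
        raise ValueError("GBI cells must be binary")
    x = x.astype(float)
    together = x.T @ x                      # F_AB
    per_bird = np.diag(together).copy()     # F_A
    denom = per_bird[:, None] + per_bird[None, :] - together
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, together / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(w, 0.0)
    return SocialNetwork(list(gbi.columns), w, period)


def network_density(net: SocialNetwork) -> float:
    """Percentage of potential dyads with a non-zero association."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density undefined for networks with < 2 nodes")
    n_edges = int(np.count_nonzero(np.triu(net.weights, k=1)))
    return 100.0 * n_edges / (n * (n - 1) / 2)


def _eigenvector_centrality(w: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the largest connected component, max-scaled.

    Nodes outside the largest component (including isolates) score 0.
    The returned vector is non-negative (Perron vector of a non-negative
    symmetric matrix) and scaled to a maximum of 1.
    """
    n = w.shape[0]
    cent = np.zeros(n)
    if n == 0 or not np.any(w):
        return cent
    n_comp, labels = connected_components(w > 0, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    comp = int(np.argmax(sizes))  # ties: lowest label = first-seen node
    idx = np.flatnonzero(labels == comp)
    if idx.size == 1:
        cent[idx] = 1.0
        return cent
    vals, vecs = np.linalg.eigh(w[np.ix_(idx, idx)])
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    cent[idx] = v / v.max()
    return cent


def node_metrics(net: SocialNetwork, gbi: pd.DataFrame,
                 detections: pd.Series | None = None) -> pd.DataFrame:
    """Per-node social measures used as model predictors.

    strength
        Sum of incident SRI weights.
    average_edge_weight
        Mean of the non-zero incident weights — missing (NaN) for
        isolated nodes rather than 0, so that "no bonds" is not
        conflated with "weak bonds".
    eigenvector_centrality
        Leading-eigenvector score (see :func:`_eigenvector_centrality`).
    mean_flock_size
        Mean size of the focal's events, counting the focal.
    n_unique_associates
        Distinct co-members across the focal's events.
    n_events, n_detections
        Number of events attended; raw antenna reads if ``detections``
        (a Series indexed by tag id) is supplied.
    """
    if list(gbi.columns) != list(net.node_ids):
        raise ValueError("network and GBI node sets differ")
    w = net.weights
    strength = w.sum(axis=1)
    degree = (w > 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        avg_edge = np.where(degree > 0, strength / np.maximum(degree, 1), np.nan)
    x = gbi.to_numpy().astype(float)
    sizes = x.sum(axis=1)                       # event sizes
    n_events = x.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_flock = np.where(n_events > 0, (x * sizes[:, None]).sum(axis=0)
                              / np.maximum(n_events, 1), np.nan)
    co_occur = (x.T @ x) > 0
    np.fill_diagonal(co_occur, False)
    out = pd.DataFrame({
        "strength": strength,
        "average_edge_weight": avg_edge,
        "eigenvector_centrality": _eigenvector_centrality(w),
        "mean_flock_size": mean_flock,
        "n_unique_associates": co_occur.sum(axis=1),
        "n_events": n_events.astype(int),
    }, index=pd.Index(net.node_ids, name="tag_id"))
    if detections is not None:
        out["n_detections"] = detections.reindex(out.index).fillna(0).astype(int)
    if net.period is not None:
        out["period"] = net.period
    # handshake identity: total strength counts every edge twice
    assert np.isclose(strength.sum(), 2 * np.triu(w, k=1).sum())
    return out


def write_edge_list(net: SocialNetwork, path) -> None:
    """Non-zero edges as ``id_a, id_b, weight`` with ``id_a < id_b``."""
    ids = np.asarray(net.node_ids)
    a, b = np.nonzero(np.triu(net.weights, k=1))
    pd.DataFrame({
        "id_a": ids[a], "id_b": ids[b],
        "weight": net.weights[a, b],
    }).to_csv(path, index=False)
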