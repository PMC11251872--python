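"""Nodal graph topology on sparsity-thresholded binary networks.

Edges are the strongest |Fisher-z| connections (top ``sparsity`` fraction);
per node we compute efficiency (harmonic mean of inverse distances, 1/inf=0),
clustering coefficient, and mean shortest path over reachable nodes.  Metrics
are recomputed per sliding window and summarized by a per-node coefficient of
variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from dynconn.dynamic_fc import WindowedFCSeries
from dynconn.static_fc import FCMatrix, upper_triangle_index

METRICS = ("efficiency", "clustering", "shortest_path")


@dataclass
class BinaryNetwork:
    adjacency: np.ndarray  # symmetric 0/1, zero diagonal
    sparsity: float
    source: str = ""

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class NodalMetricSeries:
    metric: str
    values: np.ndarray  # windows x N; NaN where undefined
    cv: np.ndarray  # per-node coefficient of variation; NaN where undefined


def binarize_by_sparsity(
    fc: FCMatrix | np.ndarray, sparsity: float = 0.2, source: str = ""
) -> BinaryNetwork:
    """Keep the top floor(sparsity * E) edges by |z|, ties broken by (i, j).

    Negative correlations enter by absolute value; weaker connections are 0.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, float)
    n = values.shape[0]
    iu = upper_triangle_index(n)
    weights = np.abs(values[iu])
    n_keep = int(np.floor(sparsity * n * (n - 1) / 2))
    # lexicographic tie-break: among equal |z|, lower (i, j) wins
    order = np.lexsort((iu[1], iu[0], -weights))
    adj = np.zeros((n, n), dtype=np.int8)
    keep = order[:n_keep]
    adj[iu[0][keep], iu[1][keep]] = 1
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, sparsity=sparsity, source=source)


def nodal_metrics(net: BinaryNetwork) -> dict[str, np.ndarray]:
    """Per-node efficiency, clustering coefficient and mean shortest path.

    Distances are breadth-first geodesics.  Efficiency uses the harmonic
    convention (1/inf = 0); clustering is 0 for degree < 2; shortest path
    averages over reachable nodes only and is NaN for isolates.
    """
    adj = net.adjacency
    n = adj.shape[0]
    dist = shortest_path(adj, method="D", unweighted=True)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & off, 1.0 / np.where(dist > 0, dist, np.inf), 0.0)
    efficiency = inv.sum(axis=1) / (n - 1)

    deg = adj.sum(axis=1)
    triangles = np.diag(adj @ adj @ adj) / 2.0
    denom = deg * (deg - 1) / 2.0
    clustering = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1.0), 0.0)

    reachable = np.isfinite(dist) & off
    n_reach = reachable.sum(axis=1)
    dsum = np.where(reachable, dist, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        spl = np.where(n_reach > 0, dsum / np.where(n_reach > 0, n_reach, 1), np.nan)
    return {
        "efficiency": efficiency,
        "clustering": clustering.astype(float),
        "shortest_path": spl,
    }


def coefficient_of_variation(
    values: np.ndarray, sample: bool = False, eps: float = 1e-9
) -> np.ndarray:
    """Per-column CV over windows, NaN-aware; columns with tiny means are NaN."""
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0, ddof=1 if sample else 0)
    out = np.full(values.shape[1], np.nan)
    ok = np.isfinite(mean) & (np.abs(mean) >= eps)
    out[ok] = sd[ok] / mean[ok]
    return out


def time_resolved_metrics(
    wfc: WindowedFCSeries, sparsity: float = 0.2, sample_sd: bool = False
) -> dict[str, NodalMetricSeries]:
    """All three nodal metrics per window plus their per-node CV."""
    if len(wfc) < 2:
        raise ValueError("need at least 2 windows for time-resolved metrics")
    n = wfc.windows[0].values.shape[0]
    per_metric = {m: np.empty((len(wfc), n)) for m in METRICS}
    for w, fc in enumerate(wfc.windows):
        net = binarize_by_sparsity(fc, sparsity, source=f"window-{w}")
        vals = nodal_metrics(net)
        for m in METRICS:
            per_metric[m][w] = vals[m]
    return {
        m: NodalMetricSeries(
            metric=m,
            values=per_metric[m],
            cv=coefficient_of_variation(per_metric[m], sample=sample_sd),
        )
        for m in METRICS
    }
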