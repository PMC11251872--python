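"""Static ROI functional connectivity and FC-matrix similarity analysis."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from dynconn.rois import RoiSet
from dynconn.synthgen import RoiTimeSeries

Z_CLIP = 1.0 - 1e-7  # |r| clipped here before atanh

SCOPES = ("all", "cortical", "subcortical", "cortico-subcortical")


@dataclass
class FCMatrix:
    """N x N symmetric Fisher-z correlation matrix (diagonal excluded)."""

    values: np.ndarray
    roi_set: RoiSet
    subject_id: str = ""
    condition: str = ""


@dataclass
class SimilarityMatrix:
    """Pairwise Pearson correlations between vectorized FC matrices."""

    values: np.ndarray
    scope: str
    level: str  # {"individual", "group"}
    ids: list[str]
    conditions: list[str]


@dataclass
class EdgeTestResult:
    t: np.ndarray  # N x N symmetric
    p: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray  # boolean N x N
    alpha: float


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """atanh with |r| clipped to 1 - 1e-7."""
    return np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))


def fc_matrix(series: RoiTimeSeries) -> FCMatrix:
    """Fisher-z Pearson correlation matrix of an ROI time-series matrix."""
    data = np.asarray(series.data, float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for a correlation matrix")
    sd = data.std(axis=0)
    if np.any(sd == 0):
        bad = [series.roi_set.names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for ROI(s): {bad}")
    z = fisher_z(np.corrcoef(data, rowvar=False))
    z = (z + z.T) / 2.0  # corrcoef is symmetric only to float rounding
    np.fill_diagonal(z, 0.0)
    return FCMatrix(
        values=z,
        roi_set=series.roi_set,
        subject_id=series.subject_id,
        condition=series.condition,
    )


def upper_triangle_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def vectorize_fc(matrix: FCMatrix, scope: str = "all") -> np.ndarray:
    """Linearize an FC matrix over an ROI scope, diagonal excluded.

    Ordering: for triangular scopes, row-major upper triangle of the selected
    block; for ``cortico-subcortical``, the full cortical x subcortical
    rectangle in row-major order (cortical rows, subcortical columns).
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    v = matrix.values
    rs = matrix.roi_set
    if scope == "all":
        return v[upper_triangle_index(len(rs))]
    if scope == "cortical":
        block = v[np.ix_(rs.cortical_idx, rs.cortical_idx)]
        return block[upper_triangle_index(len(rs.cortical_idx))]
    if scope == "subcortical":
        block = v[np.ix_(rs.subcortical_idx, rs.subcortical_idx)]
        return block[upper_triangle_index(len(rs.subcortical_idx))]
    return v[np.ix_(rs.cortical_idx, rs.subcortical_idx)].ravel()


def benjamini_hochberg(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Step-up BH procedure; returns the boolean rejection mask."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = alpha * np.arange(1, m + 1) / m
    below = np.flatnonzero(ranked <= thresh)
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up q-values)."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def edgewise_group_test(
    group_a: list[FCMatrix],
    group_b: list[FCMatrix],
    alpha: float = 0.05,
    welch: bool = False,
) -> EdgeTestResult:
    """Per-edge two-sample t-test with BH-FDR across the upper triangle.

    Equal-variance t by default (``welch=True`` for the unequal-variance
    form).  Edges with zero variance in both groups get p = 1 with a warning.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    n = len(group_a[0].roi_set)
    iu = upper_triangle_index(n)
    a = np.stack([m.values[iu] for m in group_a])
    b = np.stack([m.values[iu] for m in group_b])
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} edge(s) have zero variance in both groups; "
            "p set to 1",
            stacklevel=2,
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    p = np.nan_to_num(p, nan=1.0)
    p_adj = bh_adjust(p)
    sig = benjamini_hochberg(p, alpha)

    def to_matrix(vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        m = np.full((n, n), fill)
        m[iu] = vec
        m.T[iu] = vec
        return m

    return EdgeTestResult(
        t=to_matrix(t),
        p=to_matrix(p, fill=1.0),
        p_adj=to_matrix(p_adj, fill=1.0),
        significant=to_matrix(sig).astype(bool),
        alpha=alpha,
    )


def group_mean_fc(matrices: list[FCMatrix], condition: str) -> FCMatrix:
    vals = np.mean([m.values for m in matrices], axis=0)
    return FCMatrix(
        values=vals,
        roi_set=matrices[0].roi_set,
        subject_id=f"mean-{condition}",
        condition=condition,
    )


def similarity_analysis(
    matrices: list[FCMatrix], scope: str = "all", level: str = "individual"
) -> tuple[SimilarityMatrix, dict[tuple[str, str], float]]:
    """Pairwise Pearson similarity between vectorized FC matrices.

    Also returns a summary mapping each (condition, condition) pair to the
    Fisher-z-transformed mean similarity (mean of z(r) over pairs; the
    within-condition entry excludes self-pairs).  Zero-variance vectors make
    the affected similarities NaN (recorded as missing).
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 FC matrices")
    vecs = np.stack([vectorize_fc(m, scope) for m in matrices])
    sd = vecs.std(axis=1)
    m = len(matrices)
    sim = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            if sd[i] == 0 or sd[j] == 0:
                sim[i, j] = sim[j, i] = np.nan
                continue
            sim[i, j] = sim[j, i] = np.corrcoef(vecs[i], vecs[j])[0, 1]
    conditions = [mat.condition for mat in matrices]
    summary: dict[tuple[str, str], float] = {}
    for ca in sorted(set(conditions)):
        for cb in sorted(set(conditions)):
            if (cb, ca) in summary:
                continue
            ia = [i for i, c in enumerate(conditions) if c == ca]
            ib = [i for i, c in enumerate(conditions) if c == cb]
            vals = [
                sim[i, j]
                for i in ia
                for j in ib
                if i != j and np.isfinite(sim[i, j])
            ]
            if vals:
                summary[(ca, cb)] = float(np.mean(fisher_z(np.asarray(vals))))
    return (
        SimilarityMatrix(
            values=sim,
            scope=scope,
            level=level,
            ids=[mat.subject_id for mat in matrices],
            conditions=conditions,
        ),
        summary,
    )
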