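"""Voxel-level dynamic indices, Kendall's-W concordance and stability maps.

Five intrinsic-activity indices (fALFF, ReHo, VMHC, degree centrality,
global-signal correlation) are computed per voxel in sliding windows; their
agreement over windows (voxel-wise concordance) and over voxels (volume-wise
concordance), as well as the stability of each voxel's whole-brain FC profile
across windows, are all expressed as Kendall coefficients of concordance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from dynconn.dynamic_fc import sliding_windows
from dynconn.static_fc import bh_adjust, benjamini_hochberg, fisher_z

INDEX_NAMES = ("fALFF", "ReHo", "VMHC", "DC", "GScorr")


@dataclass
class VoxelMapSet:
    """Named per-voxel scalar maps on a common lattice mask."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    window_id: int | None = None
    subject_id: str = ""


@dataclass
class ConcordanceResult:
    voxelwise: np.ndarray  # 3-D map of W (NaN outside mask / undefined)
    volumewise_series: np.ndarray  # per-window W over voxels
    volumewise_mean: float
    voxelwise_z: np.ndarray | None = None  # atanh(W), emitted when requested


@dataclass
class GroupTestResult:
    t: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray  # signed int8: +1 increase, -1 decrease, 0 n.s.
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# Kendall's W
# ---------------------------------------------------------------------------


def _tie_term(row: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of one rater's scores."""
    _, counts = np.unique(row, return_counts=True)
    c = counts[counts > 1]
    return float((c.astype(float) ** 3 - c).sum())


def kendalls_w(scores: np.ndarray, tie_correction: bool = True) -> float:
    """Kendall's coefficient of concordance of an m-raters x n-objects matrix.

    W = 12 S / (m^2 (n^3 - n) - m * sum_i T_i), where S is the sum of squared
    deviations of object rank sums and T_i the tie term of rater i (average
    ranks assigned within ties).  Without tie correction, a rater with
    all-equal scores makes W undefined (NaN, with a warning).
    """
    scores = np.asarray(scores, float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D raters x objects matrix")
    m, n = scores.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 raters and 2 objects")
    constant = np.ptp(scores, axis=1) == 0
    if constant.any() and not tie_correction:
        warnings.warn(
            "rater(s) with all-equal scores and tie_correction off: W undefined",
            stacklevel=2,
        )
        return float("nan")
    ranks = stats.rankdata(scores, axis=1)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - m * (n + 1) / 2.0) ** 2).sum())
    tie_sum = sum(_tie_term(r) for r in scores) if tie_correction else 0.0
    denom = m * m * (n**3 - n) - m * tie_sum
    if denom <= 0:
        return float("nan")
    return 12.0 * s / denom


def _w_stack(ranks: np.ndarray, tie_sums: np.ndarray) -> np.ndarray:
    """Vectorized W for K parallel problems.

    ranks: (m, n, K) average ranks; tie_sums: (K,) summed tie terms over
    raters.  Returns (K,) W values (NaN where the denominator vanishes).
    """
    m, n, _ = ranks.shape
    rank_sums = ranks.sum(axis=0)  # (n, K)
    s = ((rank_sums - m * (n + 1) / 2.0) ** 2).sum(axis=0)
    denom = m * m * (n**3 - n) - m * tie_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, 12.0 * s / denom, np.nan)
    return w


def _tie_terms_columns(scores: np.ndarray) -> np.ndarray:
    """Tie term per column of an (n, K) score matrix (objects along axis 0)."""
    n, k = scores.shape
    srt = np.sort(scores, axis=0)
    # run-length encode equal consecutive values per column
    out = np.zeros(k)
    same = srt[1:] == srt[:-1]
    if not same.any():
        return out
    for j in np.flatnonzero(same.any(axis=0)):
        out[j] = _tie_term(scores[:, j])
    return out


# ---------------------------------------------------------------------------
# windowed intrinsic-activity indices
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray, axis: int = 0) -> np.ndarray:
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def falff(series: np.ndarray, band: tuple[float, float], tr: float) -> np.ndarray:
    """Band amplitude fraction per voxel for a (T, V) matrix, DC excluded."""
    T = series.shape[0]
    freqs = np.fft.rfftfreq(T, d=tr)
    amp = np.abs(np.fft.rfft(series, axis=0))
    in_band = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    positive = freqs > 0
    num = amp[in_band].sum(axis=0)
    den = amp[positive].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def reho_map(
    window: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Regional homogeneity: Kendall's W of each voxel with its in-mask
    26-neighborhood (raters = voxel series, objects = timepoints)."""
    from scipy import ndimage

    T = window.shape[-1]
    ranks = np.zeros(window.shape)
    flat = window[mask]  # (V, T)
    ranks[mask] = stats.rankdata(flat, axis=1)
    tie_terms = np.zeros(mask.shape)
    tie_terms[mask] = _tie_terms_columns(flat.T)

    kernel = np.ones((3, 3, 3))
    m_count = ndimage.correlate(mask.astype(float), kernel, mode="constant")
    rank_sums = np.empty_like(ranks)
    for t in range(T):
        rank_sums[..., t] = ndimage.correlate(ranks[..., t], kernel, mode="constant")
    tie_sum = ndimage.correlate(tie_terms, kernel, mode="constant")

    s = ((rank_sums - m_count[..., None] * (T + 1) / 2.0) ** 2).sum(axis=-1)
    denom = m_count**2 * (T**3 - T) - m_count * tie_sum
    out = np.full(mask.shape, np.nan)
    ok = mask & (denom > 0) & (m_count >= 2)
    out[ok] = 12.0 * s[ok] / denom[ok]
    return out


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between two (V, T) matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def windowed_indices(
    data: np.ndarray,
    gm_mask: np.ndarray,
    brain_mask: np.ndarray | None = None,
    mirror_axis: int = 0,
    width: int = 50,
    step: int = 5,
    band: tuple[float, float] = (0.01, 0.10),
    tr: float = 1.0,
    reho_data: np.ndarray | None = None,
    dc_r_threshold: float = 0.25,
    dc_alpha: float = 0.05,
    subject_id: str = "",
) -> list[VoxelMapSet]:
    """The five intrinsic-activity indices per voxel in each sliding window.

    ``data`` is the cleaned (optionally smoothed) (X, Y, Z, T) array used for
    fALFF/VMHC/DC/GScorr; ``reho_data`` (default: ``data``) should be the
    unsmoothed series, since ReHo precedes smoothing in the cleaning order.
    """
    T = data.shape[-1]
    wins = sliding_windows(T, width, step)
    if width < 2.0 / band[0]:
        warnings.warn(
            f"window of {width} samples cannot resolve the {band[0]} Hz band edge; "
            "fALFF is poorly resolved",
            stacklevel=2,
        )
    brain_mask = gm_mask if brain_mask is None else brain_mask
    reho_data = data if reho_data is None else reho_data

    gm_lin = np.flatnonzero(gm_mask.ravel())
    mirrored_mask = np.flip(gm_mask, axis=mirror_axis)
    has_mirror = gm_mask & mirrored_mask

    out: list[VoxelMapSet] = []
    for w_id, (start, end) in enumerate(wins):
        win = data[..., start:end]
        X = win.reshape(-1, width)[gm_lin]  # (V, w)

        maps: dict[str, np.ndarray] = {}

        def blank() -> np.ndarray:
            return np.full(gm_mask.shape, np.nan)

        m = blank()
        m[gm_mask] = falff(X.T, band, tr)
        maps["fALFF"] = m

        maps["ReHo"] = reho_map(reho_data[..., start:end], gm_mask)

        m = blank()
        mir = np.flip(win, axis=mirror_axis)
        r = _pearson_rows(win[has_mirror], mir[has_mirror])
        m[has_mirror] = fisher_z(r)
        maps["VMHC"] = m

        Z = _standardize(X.T, axis=0)  # (w, V)
        corr = Z.T @ Z / width
        np.fill_diagonal(corr, 0.0)
        df = width - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = corr * np.sqrt(df / np.clip(1.0 - corr**2, 1e-12, None))
        pval = 2.0 * stats.t.sf(np.abs(tval), df)
        keep = (corr > dc_r_threshold) & (pval < dc_alpha)
        m = blank()
        m[gm_mask] = (corr * keep).sum(axis=1)
        maps["DC"] = m

        gs = win[brain_mask].mean(axis=0)  # (w,)
        m = blank()
        m[gm_mask] = fisher_z(
            _pearson_rows(win[gm_mask], np.broadcast_to(gs, (gm_lin.size, width)))
        )
        maps["GScorr"] = m

        out.append(
            VoxelMapSet(maps=maps, mask=gm_mask, window_id=w_id, subject_id=subject_id)
        )
    return out


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def concordance_maps(
    windowed: list[VoxelMapSet],
    index_names: tuple[str, ...] = INDEX_NAMES,
    apply_fisher_z: bool = True,
) -> ConcordanceResult:
    """Voxel-wise and volume-wise concordance of the windowed indices.

    Voxel-wise: per voxel, Kendall's W with the indices as raters and windows
    as objects.  Volume-wise: per window, Kendall's W with indices as raters
    and in-mask voxels as objects, averaged over windows.  Voxels with fewer
    than 2 valid indices are missing.
    """
    if len(windowed) < 2:
        raise ValueError("need at least 2 windows")
    mask = windowed[0].mask
    n_win = len(windowed)
    n_idx = len(index_names)
    V = int(mask.sum())
    # scores[i, w, v]
    scores = np.empty((n_idx, n_win, V))
    for w, vm in enumerate(windowed):
        for i, name in enumerate(index_names):
            scores[i, w] = vm.maps[name][mask]

    valid = np.isfinite(scores).all(axis=1)  # (n_idx, V)
    voxel_w = np.full(V, np.nan)

    all_valid = valid.all(axis=0)
    if all_valid.any():
        sub = scores[:, :, all_valid]
        ranks = stats.rankdata(sub, axis=1)
        tie_sums = np.zeros(all_valid.sum())
        for i in range(n_idx):
            tie_sums += _tie_terms_columns(sub[i])
        voxel_w[all_valid] = _w_stack(ranks, tie_sums)
    for v in np.flatnonzero(~all_valid):
        rows = scores[valid[:, v], :, v]
        if rows.shape[0] >= 2:
            voxel_w[v] = kendalls_w(rows)

    volumewise = np.full(n_win, np.nan)
    for w in range(n_win):
        cols = valid.all(axis=0)
        mat = scores[:, w, cols]
        spatial_ok = np.isfinite(mat).all(axis=0)
        if spatial_ok.sum() >= 2:
            volumewise[w] = kendalls_w(mat[:, spatial_ok])

    vmap = np.full(mask.shape, np.nan)
    vmap[mask] = voxel_w
    zmap = None
    if apply_fisher_z:
        zmap = np.full(mask.shape, np.nan)
        zmap[mask] = fisher_z(np.clip(voxel_w, 0.0, 1.0))
    return ConcordanceResult(
        voxelwise=vmap,
        volumewise_series=volumewise,
        volumewise_mean=float(np.nanmean(volumewise)),
        voxelwise_z=zmap,
    )


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------


def stability_map(
    data: np.ndarray,
    gm_mask: np.ndarray,
    width: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Kendall's-W stability of each voxel's windowed whole-brain FC profile.

    Per voxel: the windows x (V-1) matrix of Fisher-z FC with every other
    in-mask voxel is scored with windows as raters and connections as
    objects; W = 1 means a temporally constant FC architecture.
    """
    V = int(gm_mask.sum())
    if V < 10:
        raise ValueError("gray-matter mask must contain at least 10 voxels")
    T = data.shape[-1]
    wins = sliding_windows(T, width, step)
    n_win = len(wins)
    series = data[gm_mask]  # (V, T)
    zfc = np.empty((n_win, V, V), dtype=np.float32)
    for w, (start, end) in enumerate(wins):
        Z = _standardize(series[:, start:end].T, axis=0)
        corr = np.clip(Z.T @ Z / (end - start), -1.0, 1.0)
        zfc[w] = fisher_z(corr)

    idx = np.arange(V)
    out_vals = np.empty(V)
    for v in range(V):
        others = idx != v
        profile = zfc[:, v, others].astype(float)  # (n_win, V-1)
        ranks = stats.rankdata(profile, axis=1)
        tie_sum = float(_tie_terms_columns(profile.T).sum())
        m, n = profile.shape
        s = float(((ranks.sum(axis=0) - m * (n + 1) / 2.0) ** 2).sum())
        denom = m * m * (n**3 - n) - m * tie_sum
        out_vals[v] = 12.0 * s / denom if denom > 0 else np.nan
    out = np.full(gm_mask.shape, np.nan)
    out[gm_mask] = out_vals
    return out


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def voxelwise_group_test(
    group_a: list[np.ndarray],
    group_b: list[np.ndarray],
    mask: np.ndarray,
    alpha: float = 0.05,
    paired: bool = False,
) -> GroupTestResult:
    """Per-voxel t-test between two groups of maps with BH-FDR in-mask.

    Independent-samples by default; ``paired=True`` switches to a paired test
    (groups must then be equal-sized and subject-aligned).
    """
    shapes = {m.shape for m in group_a + group_b}
    if len(shapes) != 1 or mask.shape not in shapes:
        raise ValueError("maps and mask must share one lattice")
    a = np.stack([m[mask] for m in group_a])
    b = np.stack([m[mask] for m in group_b])
    with np.errstate(invalid="ignore", divide="ignore"):
        if paired:
            if a.shape[0] != b.shape[0]:
                raise ValueError("paired test requires equal group sizes")
            t, p = stats.ttest_rel(a, b, axis=0)
        else:
            t, p = stats.ttest_ind(a, b, axis=0)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    reject = benjamini_hochberg(p, alpha)
    sig = np.sign(t).astype(np.int8) * reject

    def expand(vec: np.ndarray, fill: float) -> np.ndarray:
        out = np.full(mask.shape, fill)
        out[mask] = vec
        return out

    return GroupTestResult(
        t=expand(t, 0.0),
        p=expand(p, 1.0),
        p_adj=expand(bh_adjust(p), 1.0),
        significant=expand(sig, 0).astype(np.int8),
        alpha=alpha,
    )
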