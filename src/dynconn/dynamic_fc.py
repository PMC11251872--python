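"""Sliding-window FC and brain-state clustering.

Windowed FC matrices from all subjects and conditions are pooled and
partitioned by k-means (squared Euclidean distance); the state count is
either fixed or chosen by minimizing the Davies-Bouldin index over a range.
State occupancy frequencies and transition probabilities are then compared
across groups with one-way ANOVA and Tukey-Kramer contrasts, with
Shapiro-Wilk and Bartlett diagnostics reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from dynconn.static_fc import FCMatrix, fisher_z, upper_triangle_index
from dynconn.synthgen import RoiTimeSeries


@dataclass
class WindowedFCSeries:
    windows: list[FCMatrix]
    window_width: int
    step: int
    subject_id: str = ""
    condition: str = ""

    def __len__(self) -> int:
        return len(self.windows)

    def stack(self) -> np.ndarray:
        """windows x edges matrix (upper triangle, scope 'all')."""
        n = len(self.windows[0].roi_set)
        iu = upper_triangle_index(n)
        return np.stack([w.values[iu] for w in self.windows])


@dataclass
class StateModel:
    k: int
    centroids: np.ndarray  # k x n_edges
    labels: dict[str, np.ndarray]  # subject -> per-window state ids in 1..k
    frequencies: dict[str, np.ndarray]  # subject -> k occupancy fractions
    transition: dict[str, np.ndarray]  # subject -> k x k row-stochastic
    pooled_transition: np.ndarray
    dbi_curve: dict[int, float] = field(default_factory=dict)
    conditions: dict[str, str] = field(default_factory=dict)
    roi_names: tuple[str, ...] = ()

    def centroid_matrix(self, state: int) -> np.ndarray:
        """Reshape a centroid back to a symmetric N x N matrix."""
        n = len(self.roi_names)
        iu = upper_triangle_index(n)
        m = np.zeros((n, n))
        m[iu] = self.centroids[state - 1]
        m.T[iu] = self.centroids[state - 1]
        return m


def sliding_windows(T: int, width: int, step: int) -> list[tuple[int, int]]:
    """Half-open, 0-based [start, end) window index pairs.

    Count = floor((T - width)/step) + 1; the last window ends at or before T.
    """
    if width < 1 or step < 1:
        raise ValueError("width and step must be positive")
    if T < width:
        raise ValueError(f"series length {T} is shorter than the window width {width}")
    starts = range(0, T - width + 1, step)
    return [(s, s + width) for s in starts]


def windowed_fc(
    series: RoiTimeSeries, width: int = 50, step: int = 5
) -> WindowedFCSeries:
    """Per-window Fisher-z FC matrices, computed exactly as static FC.

    A column that is constant within a window would make its correlations
    undefined; those edges are set to z = 0 with a warning.
    """
    data = np.asarray(series.data, float)
    wins = sliding_windows(data.shape[0], width, step)
    matrices = []
    for start, end in wins:
        chunk = data[start:end]
        sd = chunk.std(axis=0)
        degenerate = sd == 0
        if degenerate.any():
            warnings.warn(
                f"window [{start},{end}) has constant column(s) "
                f"{np.flatnonzero(degenerate).tolist()}; their edges set to z=0",
                stacklevel=2,
            )
            chunk = chunk.copy()
            # give degenerate columns unit noise-free variance placeholder;
            # their correlations are zeroed below
            chunk[:, degenerate] += np.arange(chunk.shape[0])[:, None]
        with np.errstate(invalid="ignore"):
            z = fisher_z(np.corrcoef(chunk, rowvar=False))
        z = (z + z.T) / 2.0
        if degenerate.any():
            z[degenerate, :] = 0.0
            z[:, degenerate] = 0.0
        np.fill_diagonal(z, 0.0)
        matrices.append(
            FCMatrix(
                values=z,
                roi_set=series.roi_set,
                subject_id=series.subject_id,
                condition=series.condition,
            )
        )
    return WindowedFCSeries(
        windows=matrices,
        window_width=width,
        step=step,
        subject_id=series.subject_id,
        condition=series.condition,
    )


def _frequencies(labels: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(labels - 1, minlength=k) / labels.size


def transition_matrix(labels: np.ndarray, k: int) -> np.ndarray:
    """Row-stochastic transition matrix; rows with no departures are NaN."""
    counts = np.zeros((k, k))
    for a, b in zip(labels[:-1], labels[1:]):
        counts[a - 1, b - 1] += 1
    out = np.full((k, k), np.nan)
    rowsum = counts.sum(axis=1)
    defined = rowsum > 0
    out[defined] = counts[defined] / rowsum[defined, None]
    return out


def cluster_states(
    all_windows: list[WindowedFCSeries],
    k_range: range = range(2, 9),
    k_fixed: int | None = None,
    seed: int = 42,
    n_init: int = 50,
) -> StateModel:
    """Pooled k-means over every subject's windowed FC vectors.

    If ``k_fixed`` is None the state count minimizes the Davies-Bouldin index
    over ``k_range``.  An empty cluster triggers a re-run with an offset seed
    (at most 10 attempts).
    """
    if not all_windows:
        raise ValueError("no windowed FC series supplied")
    X = np.vstack([w.stack() for w in all_windows])
    sizes = [len(w) for w in all_windows]

    def fit(k: int) -> KMeans:
        for attempt in range(10):
            km = KMeans(
                n_clusters=k, n_init=n_init, random_state=seed + attempt
            ).fit(X)
            if np.bincount(km.labels_, minlength=k).min() > 0:
                return km
        raise RuntimeError(f"k-means produced an empty cluster for k={k}")

    dbi_curve: dict[int, float] = {}
    if k_fixed is None:
        fits = {}
        for k in k_range:
            if k < 2:
                continue  # DBI undefined for a single cluster
            fits[k] = fit(k)
            dbi_curve[k] = float(davies_bouldin_score(X, fits[k].labels_))
        k_best = min(dbi_curve, key=dbi_curve.get)
        km = fits[k_best]
    else:
        km = fit(k_fixed)
        k_best = k_fixed
        if k_fixed >= 2:
            dbi_curve[k_fixed] = float(davies_bouldin_score(X, km.labels_))

    labels_flat = km.labels_ + 1  # states are 1-based
    labels: dict[str, np.ndarray] = {}
    freqs: dict[str, np.ndarray] = {}
    trans: dict[str, np.ndarray] = {}
    conditions: dict[str, str] = {}
    pos = 0
    for w, size in zip(all_windows, sizes):
        sub = labels_flat[pos : pos + size]
        pos += size
        labels[w.subject_id] = sub
        freqs[w.subject_id] = _frequencies(sub, k_best)
        trans[w.subject_id] = transition_matrix(sub, k_best)
        conditions[w.subject_id] = w.condition
    pooled_counts = np.zeros((k_best, k_best))
    for sub in labels.values():
        for a, b in zip(sub[:-1], sub[1:]):
            pooled_counts[a - 1, b - 1] += 1
    pooled = np.full((k_best, k_best), np.nan)
    rowsum = pooled_counts.sum(axis=1)
    defined = rowsum > 0
    pooled[defined] = pooled_counts[defined] / rowsum[defined, None]
    return StateModel(
        k=k_best,
        centroids=km.cluster_centers_,
        labels=labels,
        frequencies=freqs,
        transition=trans,
        pooled_transition=pooled,
        dbi_curve=dbi_curve,
        conditions=conditions,
        roi_names=tuple(all_windows[0].windows[0].roi_set.names),
    )


def state_statistics(
    model: StateModel, design: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Group statistics of state frequencies plus transition summaries.

    ``design`` maps ``subject_id`` to ``group``.  Per state: one-way ANOVA of
    occupancy frequencies across groups, Tukey-Kramer pairwise contrasts, and
    Shapiro-Wilk / Bartlett diagnostics.  Transition matrices are reported
    per subject, averaged over subjects (NaN-aware, so undefined rows do not
    poison the mean), and in the pooled-count convention.
    """
    design = design.set_index("subject_id") if "subject_id" in design else design
    groups = sorted(design["group"].unique())
    freq_rows = []
    for sid, f in model.frequencies.items():
        row = {"subject_id": sid, "group": design.loc[sid, "group"]}
        row.update({f"state_{s + 1}": f[s] for s in range(model.k)})
        freq_rows.append(row)
    freq_table = pd.DataFrame(freq_rows)

    report: dict = {"k": model.k, "per_state": {}, "alpha": alpha}
    for s in range(model.k):
        col = f"state_{s + 1}"
        samples = [
            freq_table.loc[freq_table["group"] == g, col].to_numpy() for g in groups
        ]
        entry: dict = {}
        shapiro = {}
        for g, vals in zip(groups, samples):
            # states absent from every subject of a group are excluded from
            # normality diagnostics (constant zero sample)
            if len(vals) >= 3 and np.ptp(vals) > 0:
                shapiro[g] = float(stats.shapiro(vals).pvalue)
        entry["shapiro_p"] = shapiro
        nondeg = [v for v in samples if np.ptp(v) > 0]
        if len(nondeg) >= 2:
            entry["bartlett_p"] = float(stats.bartlett(*nondeg).pvalue)
        if len(groups) >= 2:
            f_stat, p = stats.f_oneway(*samples)
            entry["anova_F"] = float(f_stat)
            entry["anova_p"] = float(p)
            tk = pairwise_tukeyhsd(
                freq_table[col].to_numpy(), freq_table["group"].to_numpy(), alpha=alpha
            )
            entry["tukey"] = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0]
            ).to_dict(orient="records")
        else:
            entry["note"] = "fewer than 2 groups; ANOVA/Tukey skipped"
        report["per_state"][s + 1] = entry

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_trans = {
            g: np.nanmean(
                [
                    model.transition[sid]
                    for sid in model.transition
                    if design.loc[sid, "group"] == g
                ],
                axis=0,
            )
            for g in groups
        }
    report["mean_transition_by_group"] = {g: m.tolist() for g, m in mean_trans.items()}
    report["pooled_transition"] = model.pooled_transition.tolist()
    return {"frequencies": freq_table, "report": report}
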