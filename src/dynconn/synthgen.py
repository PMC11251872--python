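"""Synthetic multi-group BOLD generator with planted state-switching structure.

Produces ROI-level time series and small voxel lattices whose ground truth
(state sequences, covariance regimes, motion-spike frames) is returned
alongside the data, so every downstream analysis stage can be validated
without real acquisitions.

Signal model
------------
Each condition owns a library of correlation-matrix "states".  A first-order
Markov chain with configurable mean dwell time switches between states; at
each timepoint the signal is a correlated Gaussian draw (Cholesky coloring of
band-limited innovations), so the target cross-correlation is preserved
exactly within a state while the spectrum stays inside the analysis band.
White measurement noise is added on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from dynconn.rois import RoiSet, default_roi_set

#: Recognized condition names (one awake control + five anesthetic regimens).
PROFILES = ("awake", "PRO", "ISO", "KET", "DEX", "ISO-DEX")

#: Canonical state regimes; anesthetic libraries never include "rich".
STATE_IDS = ("rich", "weak", "cortical", "complex")

#: occupancy mixing per condition: the rich state is awake-dominant, the
#: globally weak and cortical-preserved states dominate the anesthetics, and
#: the complex suppressed state occurs (almost) exclusively under DEX
DEFAULT_WEIGHTS: dict[str, dict[str, float]] = {
    "awake": {"rich": 0.80, "cortical": 0.10, "weak": 0.10},
    "PRO": {"weak": 0.55, "cortical": 0.45},
    "ISO": {"weak": 0.35, "cortical": 0.65},
    "KET": {"weak": 0.50, "cortical": 0.50},
    "DEX": {"weak": 0.20, "cortical": 0.20, "complex": 0.60},
    "ISO-DEX": {"weak": 0.30, "cortical": 0.70},
}


class GenerationError(RuntimeError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class StateSpec:
    """One covariance regime: id, N x N correlation matrix, expected dwell."""

    id: str
    covariance: np.ndarray
    mean_dwell: float = 60.0

    def __post_init__(self) -> None:
        c = np.asarray(self.covariance, float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ConfigurationError("covariance must be square")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ConfigurationError("covariance must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-8):
            raise ConfigurationError("covariance must have unit diagonal")
        if np.linalg.eigvalsh(c)[0] <= 0:
            raise ConfigurationError("covariance must be positive definite")
        if self.mean_dwell < 1:
            raise ConfigurationError("mean_dwell must be >= 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the generator.  ``seed`` is mandatory for any simulation."""

    n_subjects_per_group: int = 12
    T_volumes: int = 500
    n_discard: int = 10
    tr: float = 1.0
    groups: tuple[str, ...] = PROFILES
    noise_sd: float = 0.02
    band: tuple[float, float] = (0.01, 0.10)
    mean_dwell: float = 60.0
    # state-library shape parameters
    rich_cs_r: float = 0.5
    rich_cc_r: float = 0.6
    rich_ss_r: float = 0.5
    weak_factor: float = 0.15
    suppression: float = 0.3
    dex_cortical_factor: float = 0.6
    state_weights: dict[str, dict[str, float]] | None = None
    # motion model
    spike_prob: float = 0.01
    spike_amplitude_mm: float = 0.3
    # voxel mode
    lattice_shape: tuple[int, int, int] = (12, 12, 6)
    mirror_axis: int = 0
    voxel_size: float = 0.5
    voxels_per_region: int = 8
    n_wm_voxels: int = 20
    n_csf_voxels: int = 20
    voxel_noise_sd: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.T_volumes <= self.n_discard + 50:
            raise ConfigurationError("T_volumes must exceed n_discard + 50")
        if self.lattice_shape[self.mirror_axis] % 2 != 0:
            raise ConfigurationError("lattice must be even along the mirror axis")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ConfigurationError("spike_prob must be in [0, 1]")
        unknown = set(self.groups) - set(PROFILES)
        if unknown:
            raise ConfigurationError(f"unknown condition names: {sorted(unknown)}")

    def weights_for(self, profile: str) -> dict[str, float]:
        if self.state_weights and profile in self.state_weights:
            return self.state_weights[profile]
        return DEFAULT_WEIGHTS[profile]


@dataclass
class RoiTimeSeries:
    """T x N matrix of mean BOLD signals with region metadata."""

    data: np.ndarray
    roi_set: RoiSet
    subject_id: str
    condition: str
    tr: float = 1.0

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


@dataclass
class VoxelScan:
    """4-D BOLD lattice plus label/mask volumes and a motion table."""

    bold: np.ndarray  # (X, Y, Z, T)
    labels: np.ndarray  # (X, Y, Z) uint8; 0 = unlabeled, i+1 = roi index i
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    brain_mask: np.ndarray
    motion: np.ndarray  # (T, 6): 3 translations (mm), 3 rotations (rad)
    spike_frames: np.ndarray
    roi_set: RoiSet
    subject_id: str
    condition: str
    voxel_size: float = 0.5
    mirror_axis: int = 0
    tr: float = 1.0
    state_labels: np.ndarray | None = None


@dataclass
class SimulationResult:
    subjects: list[RoiTimeSeries]
    state_labels: dict[str, np.ndarray]
    libraries: dict[str, list[StateSpec]] = field(default_factory=dict)

    def by_condition(self, condition: str) -> list[RoiTimeSeries]:
        return [s for s in self.subjects if s.condition == condition]


# ---------------------------------------------------------------------------
# state library
# ---------------------------------------------------------------------------


def repair_positive_definite(matrix: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Floor eigenvalues and rescale back to unit diagonal."""
    m = np.asarray(matrix, float)
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    if w[0] < floor:
        m = (v * np.maximum(w, floor)) @ v.T
    d = np.sqrt(np.diag(m))
    if np.any(d <= 0):
        raise GenerationError("covariance not repairable to positive-definiteness")
    m = m / np.outer(d, d)
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    if np.linalg.eigvalsh(m)[0] <= 0:
        raise GenerationError("covariance not repairable to positive-definiteness")
    return m


#: fixed seed for the deterministic within-block heterogeneity patterns;
#: part of the state definitions, independent of the simulation seed
_PATTERN_SEED = 20230517


def _heterogeneity(n_c: int, n_s: int) -> dict[str, np.ndarray]:
    """Deterministic multiplicative patterns in [0.7, 1.3] per block.

    The awake-like cortico-subcortical pattern (``x``) differs from the
    anesthetic-like one (``x2``); cortical and subcortical within-block
    patterns are shared by every state.  Without this heterogeneity the edge
    vectors of the planted states would be block-constant and FC-matrix
    similarity would be pure noise.
    """
    rng = np.random.default_rng(_PATTERN_SEED)

    def sym(n: int) -> np.ndarray:
        m = rng.uniform(0.7, 1.3, (n, n))
        return (m + m.T) / 2.0

    return {
        "cc": sym(n_c),
        "ss": sym(n_s),
        "x": rng.uniform(0.7, 1.3, (n_c, n_s)),
        "x2": rng.uniform(0.7, 1.3, (n_c, n_s)),
    }


def _assemble(
    roi_set: RoiSet,
    cc_block: np.ndarray,
    ss_block: np.ndarray,
    cs_block: np.ndarray,
) -> np.ndarray:
    n = len(roi_set)
    c = roi_set.cortical_idx
    s = roi_set.subcortical_idx
    m = np.zeros((n, n))
    m[np.ix_(c, c)] = cc_block
    m[np.ix_(s, s)] = ss_block
    m[np.ix_(c, s)] = cs_block
    m[np.ix_(s, c)] = cs_block.T
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return m


def _base_states(
    roi_set: RoiSet, config: GeneratorConfig, awake_architecture: bool = False
) -> dict[str, np.ndarray]:
    """The four regimes; ``awake_architecture`` keeps the awake
    cortico-subcortical pattern in the suppressed states (an awake brain
    drifting into low-coupling regimes retains its architecture, anesthesia
    replaces it)."""
    n_c = len(roi_set.cortical_idx)
    n_s = len(roi_set.subcortical_idx)
    h = _heterogeneity(n_c, n_s)
    cs_pattern = h["x"] if awake_architecture else h["x2"]

    rich = _assemble(
        roi_set,
        config.rich_cc_r * h["cc"],
        config.rich_ss_r * h["ss"],
        config.rich_cs_r * h["x"],
    )
    # repair first, then derive the other regimes from the repaired blocks:
    # the cortical-preserved state must share rich's cc block *exactly*
    # (planted "unchanged" edges), which a post-derivation repair would shift
    rich = repair_positive_definite(rich)
    c = roi_set.cortical_idx
    s = roi_set.subcortical_idx
    rich_cc = rich[np.ix_(c, c)].copy()
    rich_ss = rich[np.ix_(s, s)].copy()
    np.fill_diagonal(rich_cc, 0.0)
    np.fill_diagonal(rich_ss, 0.0)

    # anesthetic-like regimes share a *different* cortico-subcortical pattern
    # (x2): suppression disrupts the cross-network architecture, it does not
    # merely rescale it
    weak = _assemble(
        roi_set,
        config.weak_factor * rich_cc,
        config.weak_factor * rich_ss,
        config.weak_factor * config.rich_cs_r * cs_pattern,
    )
    cortical = _assemble(
        roi_set,
        rich_cc,  # cortico-cortical block preserved exactly
        config.suppression * rich_ss,
        config.suppression * config.rich_cs_r * cs_pattern,
    )

    # interleaved two-module checkerboard: complex but suppressed coupling
    module_c = np.arange(n_c) % 2 == 0
    module_s = np.arange(n_s) % 2 == 0

    def checker(a: np.ndarray, b: np.ndarray, hi: float, lo: float) -> np.ndarray:
        same = np.equal.outer(a, b)
        return np.where(same, hi, lo)

    complex_ = _assemble(
        roi_set,
        checker(module_c, module_c, 0.70, -0.35),
        checker(module_s, module_s, 0.70, -0.35),
        config.suppression * checker(module_c, module_s, 0.70, -0.35),
    )

    return {"rich": rich, "weak": weak, "cortical": cortical, "complex": complex_}


def build_state_library(
    roi_set: RoiSet, profile: str, config: GeneratorConfig | None = None
) -> list[StateSpec]:
    """Covariance regimes for one condition.

    The awake library is dominated by a "rich" state with strong
    cortico-subcortical coupling; anesthetic libraries contain only regimes
    whose cortico-subcortical blocks are suppressed (globally weak,
    cortical-preserved, and a complex modular pattern).  All matrices are
    repaired to positive definiteness by eigenvalue flooring.
    """
    if profile not in PROFILES:
        raise ConfigurationError(
            f"unknown profile {profile!r}; expected one of {PROFILES}"
        )
    config = config or GeneratorConfig()
    base = _base_states(roi_set, config, awake_architecture=profile == "awake")
    cort = roi_set.is_cortical
    cc = np.outer(cort, cort)

    weights = config.weights_for(profile)
    present = [sid for sid in STATE_IDS if sid in weights]
    total_w = sum(weights[sid] for sid in present)
    states = []
    for sid in present:
        m = base[sid].copy()
        if profile == "DEX" and sid != "rich":
            off = cc.copy()
            np.fill_diagonal(off, False)
            m[off] *= config.dex_cortical_factor
        # dwell scaled by 1/(1 - w) so the chain's stationary occupancy
        # equals the configured mixing weights (dominant states dwell longer)
        w = weights[sid] / total_w
        dwell = config.mean_dwell / max(1.0 - w, 1e-12) if len(present) > 1 else config.mean_dwell
        states.append(
            StateSpec(
                id=sid,
                covariance=repair_positive_definite(m),
                mean_dwell=dwell,
            )
        )
    if not states:
        raise ConfigurationError(f"profile {profile!r} has an empty state library")
    return states


def cs_block_mean_abs(matrix: np.ndarray, roi_set: RoiSet) -> float:
    """Mean |r| over the cortico-subcortical block."""
    c = roi_set.cortical_idx
    s = roi_set.subcortical_idx
    return float(np.abs(matrix[np.ix_(c, s)]).mean())


# ---------------------------------------------------------------------------
# ROI simulation
# ---------------------------------------------------------------------------


def _band_filter(
    x: np.ndarray, band: tuple[float, float], tr: float
) -> np.ndarray:
    """Hard FFT band mask per column, re-standardized to unit variance.

    A shared linear filter plus per-column rescaling preserves the
    cross-column correlation structure exactly.
    """
    T = x.shape[0]
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise GenerationError(
            f"no FFT bin falls inside the band {band} for T={T}, TR={tr}"
        )
    spec = np.fft.rfft(x, axis=0)
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=0)
    sd = out.std(axis=0)
    sd[sd == 0] = 1.0
    return out / sd


def _bandlimited_innovations(
    rng: np.random.Generator,
    T: int,
    n: int,
    band: tuple[float, float],
    tr: float,
) -> np.ndarray:
    return _band_filter(rng.standard_normal((T, n)), band, tr)


def _sample_state_sequence(
    rng: np.random.Generator,
    states: list[StateSpec],
    weights: np.ndarray,
    T: int,
) -> np.ndarray:
    k = len(states)
    if k == 1:
        return np.zeros(T, dtype=int)
    # stay with prob 1 - 1/dwell; leave proportionally to the other weights
    trans = np.zeros((k, k))
    for i, spec in enumerate(states):
        stay = max(0.0, 1.0 - 1.0 / spec.mean_dwell)
        others = weights.copy()
        others[i] = 0.0
        if others.sum() == 0:
            trans[i, i] = 1.0
            continue
        trans[i] = (1.0 - stay) * others / others.sum()
        trans[i, i] = stay
    labels = np.empty(T, dtype=int)
    s = rng.choice(k, p=weights)
    for t in range(T):
        labels[t] = s
        s = rng.choice(k, p=trans[s])
    return labels


def _simulate_subject(
    rng: np.random.Generator,
    config: GeneratorConfig,
    roi_set: RoiSet,
    states: list[StateSpec],
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    T, n = config.T_volumes, len(roi_set)
    labels = _sample_state_sequence(rng, states, weights, T)
    innov = rng.standard_normal((T, n))
    chol = [np.linalg.cholesky(s.covariance) for s in states]
    signal = np.empty_like(innov)
    for i, L in enumerate(chol):
        sel = labels == i
        if sel.any():
            signal[sel] = innov[sel] @ L.T
    # band-limit after coloring: the shared filter keeps the planted
    # correlations and makes the emitted signal exactly band-limited
    # (state switches would otherwise leak broadband sidebands)
    signal = _band_filter(signal, config.band, config.tr)
    if config.noise_sd > 0:
        signal = signal + config.noise_sd * rng.standard_normal(signal.shape)
    return signal, labels


def simulate_roi_timeseries(
    config: GeneratorConfig, roi_set: RoiSet | None = None
) -> SimulationResult:
    """Simulate ROI time series for every subject of every configured group.

    Returns the per-subject series together with the ground-truth
    per-timepoint state labels and each condition's state library.
    Identical configs (including seed) give bit-identical output.
    """
    if config.seed is None:
        raise ConfigurationError("GeneratorConfig.seed must be set for simulation")
    roi_set = roi_set or default_roi_set()
    if config.n_subjects_per_group < 2:
        warnings.warn(
            "fewer than 2 subjects per group: downstream group comparisons "
            "will be impossible",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    result = SimulationResult(subjects=[], state_labels={})
    for profile in config.groups:
        states = build_state_library(roi_set, profile, config)
        w = np.array([config.weights_for(profile)[s.id] for s in states], float)
        w = w / w.sum()
        result.libraries[profile] = states
        for i in range(config.n_subjects_per_group):
            sid = f"{profile}-{i + 1:02d}"
            data, labels = _simulate_subject(rng, config, roi_set, states, w)
            result.subjects.append(
                RoiTimeSeries(
                    data=data,
                    roi_set=roi_set,
                    subject_id=sid,
                    condition=profile,
                    tr=config.tr,
                )
            )
            result.state_labels[sid] = labels
    return result


# ---------------------------------------------------------------------------
# voxel simulation
# ---------------------------------------------------------------------------


def build_symmetric_layout(
    roi_set: RoiSet, config: GeneratorConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign mirror-symmetric voxel blocks to regions, WM and CSF.

    Returns (labels, wm_mask, csf_mask); labels holds 1-based region indices.
    """
    shape = config.lattice_shape
    ax = config.mirror_axis
    half = shape[ax] // 2
    coords = [c for c in np.ndindex(*shape) if c[ax] < half]
    need = len(roi_set) * config.voxels_per_region + config.n_wm_voxels + config.n_csf_voxels
    if need > len(coords):
        raise ConfigurationError(
            f"lattice half holds {len(coords)} voxels but the layout needs {need}"
        )

    def mirror(c: tuple[int, ...]) -> tuple[int, ...]:
        m = list(c)
        m[ax] = shape[ax] - 1 - c[ax]
        return tuple(m)

    labels = np.zeros(shape, dtype=np.uint8)
    wm = np.zeros(shape, dtype=bool)
    csf = np.zeros(shape, dtype=bool)
    pos = 0
    for r in range(len(roi_set)):
        for c in coords[pos : pos + config.voxels_per_region]:
            labels[c] = r + 1
            labels[mirror(c)] = r + 1
        pos += config.voxels_per_region
    for c in coords[pos : pos + config.n_wm_voxels]:
        wm[c] = wm[mirror(c)] = True
    pos += config.n_wm_voxels
    for c in coords[pos : pos + config.n_csf_voxels]:
        csf[c] = csf[mirror(c)] = True
    return labels, wm, csf


def validate_mirror_symmetry(labels: np.ndarray, mirror_axis: int) -> None:
    """Raise if the region layout is not mirror-symmetric."""
    flipped = np.flip(labels, axis=mirror_axis)
    bad = np.argwhere(labels != flipped)
    if bad.size:
        offenders = [tuple(int(x) for x in b) for b in bad[:10]]
        raise GenerationError(
            f"ROI layout is not mirror-symmetric; offending voxels: {offenders}"
        )


def _simulate_motion(
    rng: np.random.Generator, config: GeneratorConfig
) -> tuple[np.ndarray, np.ndarray]:
    T = config.T_volumes
    # baseline jitter with clipped increments so FD stays well below 0.15 mm
    dtrans = np.clip(0.002 * rng.standard_normal((T, 3)), -0.005, 0.005)
    drot = np.clip(0.0002 * rng.standard_normal((T, 3)), -0.0005, 0.0005)
    dtrans[0] = 0.0
    drot[0] = 0.0
    motion = np.cumsum(np.hstack([dtrans, drot]), axis=0)
    spikes = np.array([], dtype=int)
    if config.spike_prob > 0 and config.spike_amplitude_mm > 0:
        candidates = np.flatnonzero(rng.random(T) < config.spike_prob)
        spikes = candidates[candidates > 0]
        for f in spikes:
            # persistent step: exactly one FD sample exceeds the threshold
            sign = 1.0 if rng.random() < 0.5 else -1.0
            motion[f:, 0] += sign * config.spike_amplitude_mm
    return motion, spikes


def simulate_voxel_scan(
    config: GeneratorConfig,
    roi_set: RoiSet | None = None,
    profile: str = "awake",
    subject_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> VoxelScan:
    """Simulate one subject's 4-D voxel scan on a mirror-symmetric lattice.

    Every voxel of a region carries the region's ROI series plus independent
    voxel noise, so homotopic pairs share the regional signal.  WM/CSF voxels
    carry independent confound series, and the motion table contains injected
    step spikes whose framewise displacement exceeds 0.15 mm at known frames.
    """
    if config.seed is None and rng is None:
        raise ConfigurationError("GeneratorConfig.seed must be set for simulation")
    roi_set = roi_set or default_roi_set()
    rng = rng or np.random.default_rng(config.seed)

    labels, wm, csf = build_symmetric_layout(roi_set, config)
    validate_mirror_symmetry(labels, config.mirror_axis)
    gm = labels > 0
    brain = gm | wm | csf

    states = build_state_library(roi_set, profile, config)
    w = np.array([config.weights_for(profile)[s.id] for s in states], float)
    w = w / w.sum()
    roi_data, state_labels = _simulate_subject(rng, config, roi_set, states, w)

    T = config.T_volumes
    bold = np.zeros(config.lattice_shape + (T,), dtype=np.float64)
    for r in range(len(roi_set)):
        sel = labels == r + 1
        nvox = int(sel.sum())
        series = roi_data[:, r][None, :] + config.voxel_noise_sd * rng.standard_normal(
            (nvox, T)
        )
        bold[sel] = series
    for mask, scale in ((wm, 1.0), (csf, 1.0)):
        nvox = int(mask.sum())
        if nvox:
            confound = _bandlimited_innovations(rng, T, 1, config.band, config.tr)[:, 0]
            bold[mask] = scale * confound[None, :] + 0.3 * rng.standard_normal((nvox, T))

    motion, spikes = _simulate_motion(rng, config)
    return VoxelScan(
        bold=bold,
        labels=labels,
        gm_mask=gm,
        wm_mask=wm,
        csf_mask=csf,
        brain_mask=brain,
        motion=motion,
        spike_frames=spikes,
        roi_set=roi_set,
        subject_id=subject_id or f"{profile}-01",
        condition=profile,
        voxel_size=config.voxel_size,
        mirror_axis=config.mirror_axis,
        tr=config.tr,
        state_labels=state_labels,
    )


def single_state_config(config: GeneratorConfig, state_id: str) -> GeneratorConfig:
    """A copy of ``config`` whose every profile sits in one state forever."""
    return replace(
        config, state_weights={p: {state_id: 1.0} for p in PROFILES}
    )
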