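"""End-to-end orchestration: simulate -> preprocess -> static -> dynamic ->
graph -> voxel, with provenance sidecars and machine-readable reports."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dynconn import dynamic_fc, graph_metrics, io, preprocess, static_fc, synthgen, voxel_dynamics
from dynconn.rois import default_roi_set

log = logging.getLogger("dynconn")

STAGES = ("simulate", "preprocess", "static", "dynamic", "graph", "voxel")


@dataclass
class RunConfig:
    input_dir: str = "data"
    output_dir: str = "out"
    seed: int = 42
    n_subjects_per_group: int = 12
    T_volumes: int = 500
    n_discard: int = 10
    groups: tuple[str, ...] = synthgen.PROFILES
    fd_threshold: float = 0.15
    band: tuple[float, float] = (0.01, 0.10)
    fwhm: float = 0.7
    window_width: int = 50
    window_step: int = 5
    sparsity: float = 0.2
    k_fixed: int | None = None
    k_range: tuple[int, int] = (2, 8)
    n_init: int = 50
    alpha: float = 0.05
    paired: bool = False
    censor_mode: str = "interpolate"
    stages: tuple[str, ...] = ("simulate", "preprocess", "static", "dynamic", "graph")
    simulate_voxels: bool = False
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("groups", "stages", "band", "k_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def generator_config(self) -> synthgen.GeneratorConfig:
        return synthgen.GeneratorConfig(
            n_subjects_per_group=self.n_subjects_per_group,
            T_volumes=self.T_volumes,
            n_discard=self.n_discard,
            groups=self.groups,
            band=self.band,
            seed=self.seed,
        )

    def cleaning_config(self) -> preprocess.CleaningConfig:
        return preprocess.CleaningConfig(
            fd_threshold=self.fd_threshold,
            band=self.band,
            fwhm=self.fwhm,
            n_discard=self.n_discard,
            censor_mode=self.censor_mode,
        )


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def _hash_paths(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _sidecar(out_dir: Path, stage: str, params: dict, input_hash: str) -> Path:
    path = out_dir / f"{stage}.provenance.json"
    io.write_json(
        {"stage": stage, "parameters": params, "input_hash": input_hash}, path
    )
    return path


def _stage_unchanged(out_dir: Path, stage: str, params: dict, input_hash: str) -> bool:
    path = out_dir / f"{stage}.provenance.json"
    if not path.exists():
        return False
    try:
        prev = io.read_json(path)
    except (json.JSONDecodeError, OSError):
        return False
    return prev.get("parameters") == json.loads(json.dumps(params)) and prev.get(
        "input_hash"
    ) == input_hash


def validate_inputs(input_dir: str | Path, design: pd.DataFrame) -> ValidationReport:
    """Readability / consistency checks; always returns a report."""
    report = ValidationReport()
    input_dir = Path(input_dir)
    roi_set = default_roi_set()
    for _, row in design.iterrows():
        sid = row["subject_id"]
        tsv = input_dir / f"{sid}.tsv"
        if not tsv.exists():
            report.fatal.append(f"{sid}: missing ROI series {tsv.name}")
            continue
        try:
            ts = io.read_roi_tsv(tsv, roi_set, subject_id=sid)
        except ValueError as exc:
            report.fatal.append(f"{sid}: {exc}")
            continue
        motion_path = input_dir / f"{sid}_motion.txt"
        if motion_path.exists():
            motion = io.read_motion(motion_path)
            if motion.shape[0] != ts.n_timepoints:
                report.fatal.append(
                    f"{sid}: motion table has {motion.shape[0]} rows, "
                    f"expected {ts.n_timepoints}"
                )
    if design["group"].value_counts().min() < 2:
        report.warnings.append("some group has fewer than 2 subjects")
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report.

    Every stage writes a provenance sidecar (parameters + input hash); a
    stage whose inputs and parameters are unchanged is skipped unless
    ``config.force`` is set.
    """
    input_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed}
    roi_set = default_roi_set()

    if "simulate" in config.stages:
        params = {"seed": config.seed, "n": config.n_subjects_per_group,
                  "T": config.T_volumes, "groups": list(config.groups)}
        if config.force or not _stage_unchanged(out_dir, "simulate", params, ""):
            input_dir.mkdir(parents=True, exist_ok=True)
            gen = config.generator_config()
            sim = synthgen.simulate_roi_timeseries(gen, roi_set)
            rows = []
            for ts in sim.subjects:
                io.write_roi_tsv(ts, input_dir / f"{ts.subject_id}.tsv")
                rows.append((ts.subject_id, ts.condition))
            io.write_design(rows, input_dir / "design.csv")
            io.write_json(
                {sid: [int(x) for x in lab] for sid, lab in sim.state_labels.items()},
                input_dir / "state_truth.json",
            )
            if config.simulate_voxels:
                rng = np.random.default_rng(config.seed + 1)
                for profile in config.groups:
                    scan = synthgen.simulate_voxel_scan(
                        gen, roi_set, profile=profile,
                        subject_id=f"{profile}-vox-01", rng=rng,
                    )
                    io.write_voxel_scan(scan, input_dir / "voxels")
            _sidecar(out_dir, "simulate", params, "")
            report["stages"]["simulate"] = {
                "n_subjects": config.n_subjects_per_group * len(config.groups)
            }
        else:
            report["stages"]["simulate"] = {"skipped": "unchanged"}

    design_path = input_dir / "design.csv"
    design = io.read_design(design_path) if design_path.exists() else None

    def needs(stage: str) -> pd.DataFrame:
        if design is None:
            raise FileNotFoundError(
                f"stage '{stage}' requires {design_path}, which is missing"
            )
        return design

    cleaned: dict[str, synthgen.RoiTimeSeries] = {}
    if "preprocess" in config.stages:
        d = needs("preprocess")
        cfg = config.cleaning_config()
        clean_dir = out_dir / "cleaned"
        clean_dir.mkdir(exist_ok=True)
        for _, row in d.iterrows():
            sid = row["subject_id"]
            ts = io.read_roi_tsv(input_dir / f"{sid}.tsv", roi_set, sid, row["group"])
            data = ts.data[cfg.n_discard:]
            motion_path = input_dir / f"{sid}_motion.txt"
            if motion_path.exists():
                motion = io.read_motion(motion_path)[cfg.n_discard:]
                fd = preprocess.framewise_displacement(motion, cfg.rotation_radius)
                data, _ = preprocess.censor_frames(
                    data, fd, cfg.fd_threshold, cfg.censor_mode
                )
                confounds = motion
            else:
                confounds = None
            data = preprocess.clean_timeseries(data, confounds, cfg)
            ts = synthgen.RoiTimeSeries(data, roi_set, sid, row["group"], ts.tr)
            cleaned[sid] = ts
            io.write_roi_tsv(ts, clean_dir / f"{sid}.tsv")
        params = {"band": list(cfg.band), "fd": cfg.fd_threshold,
                  "n_discard": cfg.n_discard, "mode": cfg.censor_mode}
        _sidecar(out_dir, "preprocess", params,
                 _hash_paths(sorted(input_dir.glob("*.tsv"))))
        report["stages"]["preprocess"] = {
            "n_subjects": len(cleaned),
            "timepoints": next(iter(cleaned.values())).n_timepoints if cleaned else 0,
        }

    def load_cleaned() -> dict[str, synthgen.RoiTimeSeries]:
        if cleaned:
            return cleaned
        d = needs("cleaned series")
        clean_dir = out_dir / "cleaned"
        if not clean_dir.exists():
            raise FileNotFoundError(
                "enabled stage needs cleaned series; run the preprocess stage first"
            )
        return {
            row["subject_id"]: io.read_roi_tsv(
                clean_dir / f"{row['subject_id']}.tsv", roi_set,
                row["subject_id"], row["group"],
            )
            for _, row in d.iterrows()
        }

    if "static" in config.stages:
        d = needs("static")
        series = load_cleaned()
        fcs = [static_fc.fc_matrix(ts) for ts in series.values()]
        fc_dir = out_dir / "static"
        fc_dir.mkdir(exist_ok=True)
        for fc in fcs:
            io.write_matrix_tsv(
                fc.values, fc_dir / f"{fc.subject_id}_fc.tsv", list(roi_set.names)
            )
        edge_summary = {}
        awake = [f for f in fcs if f.condition == "awake"]
        if len(awake) >= 2:
            for cond in sorted({f.condition for f in fcs} - {"awake"}):
                grp = [f for f in fcs if f.condition == cond]
                if len(grp) < 2:
                    continue
                res = static_fc.edgewise_group_test(awake, grp, config.alpha)
                edge_summary[cond] = int(res.significant[np.triu_indices(len(roi_set), 1)].sum())
        similarity = {}
        for scope in static_fc.SCOPES:
            sim, summary = static_fc.similarity_analysis(fcs, scope)
            io.write_matrix_tsv(sim.values, fc_dir / f"similarity_{scope}.tsv", sim.ids)
            similarity[scope] = {f"{a}|{b}": v for (a, b), v in summary.items()}
        report["stages"]["static"] = {
            "significant_edges_vs_awake": edge_summary,
            "similarity_mean_z": similarity,
        }
        _sidecar(out_dir, "static", {"alpha": config.alpha}, "")

    model = None
    wfc_by_subject: dict[str, dynamic_fc.WindowedFCSeries] = {}
    if "dynamic" in config.stages or "graph" in config.stages:
        series = load_cleaned()
        for sid, ts in series.items():
            wfc_by_subject[sid] = dynamic_fc.windowed_fc(
                ts, config.window_width, config.window_step
            )

    if "dynamic" in config.stages:
        d = needs("dynamic")
        model = dynamic_fc.cluster_states(
            list(wfc_by_subject.values()),
            k_range=range(config.k_range[0], config.k_range[1] + 1),
            k_fixed=config.k_fixed,
            seed=config.seed,
            n_init=config.n_init,
        )
        stats_out = dynamic_fc.state_statistics(model, d, config.alpha)
        dyn_dir = out_dir / "dynamic"
        dyn_dir.mkdir(exist_ok=True)
        rows = [
            {"subject_id": sid, "window": w, "state": int(s)}
            for sid, lab in model.labels.items()
            for w, s in enumerate(lab)
        ]
        pd.DataFrame(rows).to_csv(dyn_dir / "state_assignments.csv", index=False)
        stats_out["frequencies"].to_csv(dyn_dir / "state_frequencies.csv", index=False)
        for s in range(1, model.k + 1):
            io.write_matrix_tsv(
                model.centroid_matrix(s), dyn_dir / f"centroid_state{s}.tsv",
                list(roi_set.names),
            )
        io.write_json(stats_out["report"], dyn_dir / "state_stats.json")
        report["stages"]["dynamic"] = {
            "k": model.k,
            "dbi_curve": model.dbi_curve,
            "windows_per_subject": {
                sid: len(w) for sid, w in wfc_by_subject.items()
            },
        }
        _sidecar(out_dir, "dynamic", {
            "width": config.window_width, "step": config.window_step,
            "seed": config.seed, "n_init": config.n_init,
        }, "")

    if "graph" in config.stages:
        graph_dir = out_dir / "graph"
        graph_dir.mkdir(exist_ok=True)
        cv_rows = []
        for sid, wfc in wfc_by_subject.items():
            metrics = graph_metrics.time_resolved_metrics(wfc, config.sparsity)
            for name, series_ in metrics.items():
                pd.DataFrame(series_.values, columns=list(roi_set.names)).to_csv(
                    graph_dir / f"{sid}_{name}.tsv", sep="\t", index=False
                )
                row = {"subject_id": sid, "metric": name}
                row.update(dict(zip(roi_set.names, series_.cv)))
                cv_rows.append(row)
        pd.DataFrame(cv_rows).to_csv(graph_dir / "cv_summary.csv", index=False)
        report["stages"]["graph"] = {"sparsity": config.sparsity,
                                     "n_subjects": len(wfc_by_subject)}
        _sidecar(out_dir, "graph", {"sparsity": config.sparsity}, "")

    if "voxel" in config.stages:
        vox_dir = input_dir / "voxels"
        if not vox_dir.exists():
            raise FileNotFoundError(
                "stage 'voxel' needs simulated voxel scans; enable simulate_voxels"
            )
        cfg = config.cleaning_config()
        voxel_summary = {}
        for truth_file in sorted(vox_dir.glob("*_truth.json")):
            sid = truth_file.name.replace("_truth.json", "")
            bold = io.read_nifti(vox_dir / f"{sid}_bold.nii").astype(float)
            gm = io.read_nifti(vox_dir / f"{sid}_gm_mask.nii").astype(bool)
            wm = io.read_nifti(vox_dir / f"{sid}_wm_mask.nii").astype(bool)
            csf = io.read_nifti(vox_dir / f"{sid}_csf_mask.nii").astype(bool)
            brain = io.read_nifti(vox_dir / f"{sid}_brain_mask.nii").astype(bool)
            motion = io.read_motion(vox_dir / f"{sid}_motion.txt")
            truth = io.read_json(truth_file)
            bold = bold[..., cfg.n_discard:]
            motion = motion[cfg.n_discard:]
            fd = preprocess.framewise_displacement(motion, cfg.rotation_radius)
            flat = bold.reshape(-1, bold.shape[-1]).T
            flat, _ = preprocess.censor_frames(flat, fd, cfg.fd_threshold, "interpolate")
            confounds = np.column_stack([
                flat[:, wm.ravel()].mean(axis=1),
                flat[:, csf.ravel()].mean(axis=1),
                motion,
            ])
            flat = preprocess.clean_timeseries(flat, confounds, cfg)
            clean = flat.T.reshape(bold.shape)
            smoothed = preprocess.gaussian_smooth(clean, cfg.fwhm, 0.5, brain)
            win = voxel_dynamics.windowed_indices(
                smoothed, gm, brain, truth["mirror_axis"],
                config.window_width, config.window_step, cfg.band,
                reho_data=clean, subject_id=sid,
            )
            conc = voxel_dynamics.concordance_maps(win)
            stab = voxel_dynamics.stability_map(
                clean, gm, config.window_width, config.window_step
            )
            io.write_nifti(conc.voxelwise, out_dir / f"{sid}_concordance.nii")
            io.write_nifti(stab, out_dir / f"{sid}_stability.nii")
            voxel_summary[sid] = {
                "volumewise_concordance": conc.volumewise_mean,
                "mean_stability": float(np.nanmean(stab)),
            }
        report["stages"]["voxel"] = voxel_summary
        _sidecar(out_dir, "voxel", {"width": config.window_width}, "")

    io.write_json(_jsonable(report), out_dir / "report.json")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
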