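"""End-to-end pipeline: lift a keypoint file, then optional OKS and gait.

A :class:`PipelineConfig` (usually loaded from YAML) names the input files
and per-stage settings; :func:`run_pipeline` validates it, executes
lift -> optional 2D evaluation -> optional gait extraction, writes the
stage outputs, and returns a machine-readable run summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .gait import FootTrace, individual_strides
from .geometry import load_calibration
from .io import read_keypoints, write_poses
from .metrics import OksConfig, accuracy_at_threshold, oks
from .optimize import EnergyConfig, lift_sequence
from .priors import load_prior
from .skeleton import build_default_mouse_skeleton

__all__ = ["PipelineConfig", "run_pipeline", "foot_trace_from_records"]


@dataclass
class GaitBlock:
    belt_speed_mm_s: float = 240.0
    fps: float = 30.0
    joint: str = "left_ankle"
    outlier_sigma: float = 2.3
    motion_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)


@dataclass
class PipelineConfig:
    keypoints: str
    calibration: str
    pose_prior: str | None = None
    shape_prior: str | None = None
    output_dir: str = "."
    fixed_distance_mm: float = 370.0
    energy: dict = field(default_factory=dict)
    oks_truth: str | None = None
    oks_thresholds: tuple[float, ...] = (0.5, 0.7, 0.9)
    gait: GaitBlock | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        gait = doc.pop("gait", None)
        cfg = cls(**doc)
        if gait is not None:
            cfg.gait = GaitBlock(**gait)
        return cfg

    def validate(self) -> None:
        for label, p in [("keypoints", self.keypoints),
                         ("calibration", self.calibration),
                         ("pose_prior", self.pose_prior),
                         ("shape_prior", self.shape_prior),
                         ("oks_truth", self.oks_truth)]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")

    def energy_config(self) -> EnergyConfig:
        return EnergyConfig(fixed_distance=self.fixed_distance_mm,
                            seed=self.seed, **self.energy)


def foot_trace_from_records(records: list[dict], joint: str, fps: float,
                            motion_axis=(1.0, 0.0, 0.0)) -> FootTrace:
    """Project a reconstructed joint onto the treadmill motion axis."""
    axis = np.asarray(motion_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    samples = []
    for rec in records:
        joints = rec.get("joints_mm")
        if joints is None or joint not in joints:
            samples.append(np.nan)
        else:
            samples.append(float(np.asarray(joints[joint]) @ axis))
    samples = np.asarray(samples)
    if np.any(np.isnan(samples)):  # fill gaps by previous value
        for i in range(samples.size):
            if np.isnan(samples[i]):
                samples[i] = samples[i - 1] if i else 0.0
    return FootTrace(samples=samples, fps=fps, joint_name=joint)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run summary."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    skeleton = build_default_mouse_skeleton()
    summary: dict = {"version": __version__, "seed": config.seed,
                     "stages": []}

    # -- lift ------------------------------------------------------------
    frames = read_keypoints(config.keypoints, skeleton.keypoint_names)
    camera = load_calibration(config.calibration)
    pose_prior = load_prior(config.pose_prior) if config.pose_prior else None
    shape_prior = (load_prior(config.shape_prior)
                   if config.shape_prior else None)
    fits = lift_sequence(frames, camera, skeleton, pose_prior, shape_prior,
                         config.energy_config())
    poses_path = out_dir / "poses.jsonl"
    write_poses(poses_path, fits, skeleton)
    n_conv = sum(f.converged for f in fits)
    rmses = [f.final_reprojection_rmse for f in fits if f.pose is not None]
    summary["stages"].append("lift")
    summary["lift"] = {
        "n_frames": len(fits),
        "n_converged": n_conv,
        "convergence_rate": n_conv / len(fits) if fits else 0.0,
        "mean_reprojection_rmse_px": float(np.mean(rmses)) if rmses else None,
        "output": str(poses_path),
    }

    # -- optional 2D evaluation -------------------------------------------
    if config.oks_truth:
        truth = read_keypoints(config.oks_truth, skeleton.keypoint_names)
        n = min(len(truth), len(frames))
        cfg = OksConfig(n_keypoints=len(skeleton.keypoint_names))
        results = [oks(frames[i], truth[i], config=cfg) for i in range(n)]
        table = {f"T={t}": accuracy_at_threshold(results, t)
                 for t in config.oks_thresholds}
        oks_path = out_dir / "oks.json"
        with open(oks_path, "w") as fh:
            json.dump(table, fh, indent=1)
        summary["stages"].append("eval-oks")
        summary["oks"] = {"n_frames": n, "output": str(oks_path),
                          "mean_aggregate": float(np.mean(
                              [r.aggregate for r in results]))}

    # -- optional gait ----------------------------------------------------
    if config.gait is not None:
        from .io import read_poses
        records = read_poses(poses_path)
        trace = foot_trace_from_records(records, config.gait.joint,
                                        config.gait.fps,
                                        config.gait.motion_axis)
        strides = individual_strides(trace, config.gait.belt_speed_mm_s,
                                     outlier_sigma=config.gait.outlier_sigma)
        gait_path = out_dir / "gait.csv"
        import pandas as pd
        pd.DataFrame({
            "duration_s": strides.individual_durations_s,
            "length_mm": strides.individual_lengths_mm,
            "outlier": strides.outlier_mask,
        }).to_csv(gait_path, index=False)
        summary["stages"].append("gait")
        summary["gait"] = {
            "peak_frequency_hz": strides.peak_frequency_hz,
            "aggregate_stride_length_mm": strides.aggregate_stride_length_mm,
            "n_strides": int(strides.individual_lengths_mm.size),
            "n_outliers": int(strides.outlier_mask.sum()),
            "output": str(gait_path),
        }

    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
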