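"""End-to-end pipeline: simulate (or load), preprocess, project, overlay.

One YAML-serializable :class:`PipelineConfig` drives the whole chain and a
single top-level seed feeds every source of randomness.  ``run_pipeline``
writes all artifacts (HDF5 volume pair, C-/B-scan TIFF+PNG, histogram CSVs,
overlay renderings) plus a machine-readable ``report.json`` of every
computed statistic.  The report is fully deterministic for a fixed
(config, seed); wall-clock stage timings go to a ``timings.json`` sidecar
so they never perturb the canonical report.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field

from sampam import analytics, overlay as overlay_mod, preprocess
from sampam.io_hdf5 import write_volume
from sampam.phantom import (PhantomConfig, TransducerConfig, generate_phantom,
                            simulate_pam, simulate_sam)

__all__ = ["PipelineConfig", "run_pipeline", "describe_run"]


class WindowConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    #: "full" keeps everything; "manual" uses [start, end] on the aligned
    #: axis; "auto" centres on the strongest SAM envelope peak with guards.
    mode: str = "auto"
    start: float | None = None
    end: float | None = None
    guard_before: float = 1.7e-3
    guard_after: float = 0.4e-3


class PreprocessParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pre_trigger_samples: int = Field(default=64, ge=1)
    window: WindowConfig = Field(default_factory=WindowConfig)


class AlignParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sound_speed: float = Field(default=1500.0, gt=0)
    reference: str = "depth"


class AnalyticsParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bscan_line: int | None = None          # default: centre lateral line
    occupancy_threshold: float | None = None  # default: noise-window derived
    noise_fraction: float = Field(default=0.1, gt=0, le=1)
    contrast_fg_level: float = Field(default=0.5, gt=0, lt=1)
    contrast_bg_level: float = Field(default=0.2, gt=0, lt=1)


class OverlayParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "blend"
    lut_size: int = Field(default=256, ge=2)
    azimuth: float = 30.0
    elevation: float = 30.0


class PipelineConfig(BaseModel):
    """Complete declarative description of one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    transducer: TransducerConfig = Field(default_factory=TransducerConfig)
    preprocess: PreprocessParams = Field(default_factory=PreprocessParams)
    align: AlignParams = Field(default_factory=AlignParams)
    analytics: AnalyticsParams = Field(default_factory=AnalyticsParams)
    overlay: OverlayParams = Field(default_factory=OverlayParams)
    output_dir: str = "sampam_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            payload = yaml.safe_load(f) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(json.loads(self.model_dump_json()), f,
                           sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = json.loads(self.model_dump_json(exclude={"output_dir"}))
        canonical = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _save_scan_images(data: np.ndarray, stem: Path, cmap: str) -> list[str]:
    """Export one 2-D scan as 16-bit TIFF (raw scale) and colormapped PNG."""
    peak = float(data.max())
    scaled = (data / peak * 65535.0).astype(np.uint16) if peak > 0 \
        else np.zeros(data.shape, dtype=np.uint16)
    tif, png = stem.with_suffix(".tiff"), stem.with_suffix(".png")
    tifffile.imwrite(tif, scaled)
    plt.imsave(png, data.T, cmap=cmap, origin="lower")
    return [tif.name, png.name]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts; return the run report.

    The top-level seed overrides the phantom seed so one number controls
    all randomness.  Stage failures are re-raised with the stage name
    prepended for provenance.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    report: dict = {"schema_version": "1", "config_hash": cfg_hash,
                    "seed": config.seed, "stages": [], "statistics": {},
                    "artifacts": []}
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        # -- simulate -----------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        phantom_cfg = config.phantom.model_copy(update={"seed": config.seed})
        phantom = generate_phantom(phantom_cfg)
        sam = simulate_sam(phantom, config.transducer)
        pam = simulate_pam(phantom, config.transducer,
                           n_samples=sam.n_samples)
        h5_path = out / "volumes.h5"
        if h5_path.exists():
            h5_path.unlink()
        write_volume(sam, h5_path)
        write_volume(pam, h5_path)
        import h5py
        with h5py.File(h5_path, "a") as f:
            f.attrs["description"] = (
                f"SAM/PAM phantom volume pair (config {cfg_hash})")
        report["artifacts"].append(h5_path.name)
        report["stages"].append({"name": stage,
                                 "pigment_cells": len(phantom.pigment_cells),
                                 "scales": len(phantom.scales),
                                 "sam_report": sam.report,
                                 "pam_report": pam.report})
        timings[stage] = time.perf_counter() - t0

        # -- preprocess + co-register ------------------------------------
        stage = "preprocess"
        t0 = time.perf_counter()
        pre = config.preprocess.pre_trigger_samples
        sam = preprocess.subtract_bias(sam, pre)
        pam = preprocess.subtract_bias(pam, pre)
        env_sam, env_pam = preprocess.align_and_coregister(
            sam, pam, sound_speed=config.align.sound_speed,
            reference=config.align.reference)
        wc = config.preprocess.window
        if wc.mode == "manual":
            window = preprocess.TimeWindow(wc.start, wc.end)
        elif wc.mode == "auto":
            window = preprocess.auto_window(env_sam, wc.guard_before,
                                            wc.guard_after)
        elif wc.mode == "full":
            window = preprocess.TimeWindow(
                max(0.0, float(env_sam.depth_axis[0])),
                float(env_sam.depth_axis[-1]))
        else:
            raise ValueError(f"unknown window mode {wc.mode!r}")
        env_sam = preprocess.apply_window(env_sam, window)
        env_pam = preprocess.apply_window(env_pam, window)
        report["stages"].append({
            "name": stage,
            "window": [window.start, window.end],
            "depth_samples": int(env_sam.data.shape[2]),
        })
        timings[stage] = time.perf_counter() - t0

        # -- analytics ----------------------------------------------------
        stage = "analytics"
        t0 = time.perf_counter()
        full = preprocess.TimeWindow(
            max(0.0, float(env_sam.depth_axis[0])),
            float(env_sam.depth_axis[-1]))
        line = config.analytics.bscan_line
        if line is None:
            line = env_sam.data.shape[1] // 2
        stats: dict = {}
        for name, env in (("sam", env_sam), ("pam", env_pam)):
            cscan = analytics.cscan_map(env, full)
            bscan = analytics.extract_bscan(env, line)
            report["artifacts"] += _save_scan_images(
                cscan.data, out / f"cscan_{name}",
                "gray" if name == "sam" else "hot")
            report["artifacts"] += _save_scan_images(
                bscan.data, out / f"bscan_{name}",
                "gray" if name == "sam" else "hot")
            hist = analytics.volume_histogram(env)
            hist_path = out / f"histogram_{name}.csv"
            with open(hist_path, "w", newline="") as f:
                w = csv.writer(f)
                w.writerow(["bin_start", "bin_end", "count"])
                w.writerows(hist.to_rows())
            report["artifacts"].append(hist_path.name)

            thr = config.analytics.occupancy_threshold
            if thr is None:
                n_noise = max(1, int(config.analytics.noise_fraction
                                     * len(env.depth_axis)))
                noise_win = preprocess.TimeWindow(
                    max(0.0, float(env.depth_axis[0])),
                    float(env.depth_axis[n_noise - 1])
                    if n_noise > 1 else float(env.depth_axis[0]) + 1e-12)
                thr = analytics.noise_threshold(env, noise_win)
            stats[f"occupancy_percent_{name}"] = analytics.occupancy_fraction(
                env, thr)
            stats[f"occupancy_threshold_{name}"] = thr

            peak = float(cscan.data.max())
            fg = cscan.data > config.analytics.contrast_fg_level * peak
            bg = cscan.data <= config.analytics.contrast_bg_level * peak
            if peak > 0 and fg.any() and bg.any():
                stats[f"contrast_ratio_{name}"] = analytics.contrast_ratio(
                    cscan, fg, bg)
            else:
                stats[f"contrast_ratio_{name}"] = None
            stats[f"cscan_local_maxima_{name}"] = analytics.count_local_maxima(
                cscan)
        report["statistics"] = stats
        report["stages"].append({"name": stage, "bscan_line": line})
        timings[stage] = time.perf_counter() - t0

        # -- overlay ------------------------------------------------------
        stage = "overlay"
        t0 = time.perf_counter()
        maps = overlay_mod.build_colormaps(n=config.overlay.lut_size)
        fused = overlay_mod.compose_overlay(env_sam, env_pam, maps,
                                            mode=config.overlay.mode)
        for view in ("side", "angular"):
            img = overlay_mod.render_views(
                fused, view=view, azimuth=config.overlay.azimuth,
                elevation=config.overlay.elevation)
            path = out / f"overlay_{view}.png"
            plt.imsave(path, img)
            report["artifacts"].append(path.name)
        report["stages"].append({"name": stage, "mode": config.overlay.mode,
                                 "lut_rows": int(maps.combined_lut.shape[0])})
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed "
                           f"(config {cfg_hash}): {exc}") from exc

    report_path = out / "report.json"
    with open(report_path, "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
    with open(out / "timings.json", "w") as f:
        json.dump({"seconds": timings}, f, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    return report


def describe_run(report_path: str | Path) -> str:
    """Human-readable summary of a pipeline report: stages, stats, files."""
    report_path = Path(report_path)
    if not report_path.exists():
        raise FileNotFoundError(f"no report at {report_path}")
    try:
        with open(report_path) as f:
            report = json.load(f)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt JSON report {report_path}: {exc}") from exc

    lines = [f"run report {report_path}",
             f"  config hash: {report.get('config_hash', '?')}",
             f"  seed: {report.get('seed', '?')}"]
    stages = report.get("stages", [])
    if not stages:
        lines.append("  no stages recorded")
    timings = {}
    timing_path = report_path.parent / "timings.json"
    if timing_path.exists():
        with open(timing_path) as f:
            timings = json.load(f).get("seconds", {})
    for s in stages:
        name = s.get("name", "?")
        t = f" [{timings[name]:.2f} s]" if name in timings else ""
        extras = {k: v for k, v in s.items() if k != "name"}
        lines.append(f"  stage {name}{t}: {extras}")
    stats = report.get("statistics", {})
    for k in sorted(stats):
        lines.append(f"  {k} = {stats[k]}")
    arts = report.get("artifacts", [])
    lines.append(f"  artifacts ({len(arts)}): {', '.join(arts)}")
    return "\n".join(lines)
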