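"""End-to-end orchestration: phantom -> reconstruction -> measurement ->
mechanics -> causality, with serialized intermediate products and a
summary report.

A run is reproducible from its :class:`RunConfig` plus the root seed: all
stage randomness (phantom speckle, acquisition start phases, replicate
perturbations) derives from the one seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .causality import causality_table, low_resistance_window
from .errors import InsufficientDataError, TubepumpError
from .lumen_measure import (
    CLOSURE_AREA_UM2,
    SegmentationConfig,
    area_trace,
    extract_plane_image,
    place_planes,
    segment_lumen,
)
from .mechanics import (
    HemodynamicSeries,
    classify_mechanism,
    flow_resistance,
    label_phases,
    pressure_gradient,
    volumetric_flow_rate,
)
from .oct_recon import Volume4D, gate_and_synchronize
from .phantom import acquire, random_plan
from .scenarios import Scenario, outflow_like, ventricle_like

log = logging.getLogger("tubepump")

SCENARIO_FACTORIES = {
    "ventricle_like": ventricle_like,
    "outflow_like": outflow_like,
}


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    mode: str = "phantom"  # phantom | import
    scenario: str = "ventricle_like"
    scenario_overrides: dict = field(default_factory=dict)
    import_volume_path: str | None = None
    import_mask_paths: dict = field(default_factory=dict)  # plane label -> TIFF path
    seed: int = 0
    plane_spacing_um: float = 30.0
    plane_axis: list | None = None  # [origin_um(3), direction(3)] for import mode
    kasai_window: list = field(default_factory=lambda: [3, 3])
    segmentation: dict = field(default_factory=dict)
    theta_deg: float | None = None  # None: take from phantom metadata
    angle_correction: str = "divide"
    resistance_threshold: float = 0.1
    lags: list = field(default_factory=lambda: [1, 2, 3])
    peak_speed_min_area_frac: float = 0.25
    save_frames: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def compare_flow_to_wave_speed(
    v_series_um3_s: np.ndarray,
    areas_um2: np.ndarray,
    wave_speed_mm_s: float,
    min_area_frac: float = 0.25,
) -> dict:
    """Averaged peak blood-flow speed at the flow plane vs the wall wave speed.

    The flow speed is the cross-section mean ``V(t) / A(t)`` in mm/s,
    and its peak is taken over phases where the flow plane is reliably
    open (area at least ``min_area_frac`` of the cycle maximum) — speed
    readings through a nearly closed aperture are transit artifacts, not
    transport. If no phase qualifies, the nearest open phase to the flux
    peak is used.
    """
    if wave_speed_mm_s <= 0:
        raise ValueError("wave speed must be positive")
    v = np.asarray(v_series_um3_s, dtype=float)
    a = np.asarray(areas_um2, dtype=float)
    if not np.any(np.abs(v) > 0):
        return {"peak_speed_mm_s": 0.0, "wave_speed_mm_s": wave_speed_mm_s, "ratio": 0.0}
    ok = a >= min_area_frac * a.max()
    if not ok.any():
        open_idx = np.nonzero(a > 0)[0]
        if len(open_idx) == 0:
            return {"peak_speed_mm_s": 0.0, "wave_speed_mm_s": wave_speed_mm_s, "ratio": 0.0}
        ok = np.zeros_like(ok)
        ok[open_idx[np.argmin(np.abs(open_idx - np.argmax(np.abs(v))))]] = True
    speed = np.abs(v[ok]) / a[ok] * 1e-3  # um/s -> mm/s
    peak = float(speed.max())
    return {
        "peak_speed_mm_s": peak,
        "wave_speed_mm_s": float(wave_speed_mm_s),
        "ratio": peak / wave_speed_mm_s,
    }


def build_scenario(config: RunConfig) -> Scenario:
    if config.scenario not in SCENARIO_FACTORIES:
        raise TubepumpError(f"unknown scenario {config.scenario!r}")
    overrides = dict(config.scenario_overrides)
    # one root seed drives everything: wall irregularity and nuisance flow
    # realizations as well as speckle and acquisition phases
    overrides.setdefault("drive_seed", config.seed)
    return SCENARIO_FACTORIES[config.scenario](**overrides)


def _volume_planes(vol: Volume4D, scenario: Scenario | None, config: RunConfig):
    """Measurement planes in volume physical coordinates (slice, depth, lateral)."""
    sizes = vol.pixel_sizes_um
    ny, nx = vol.structural.shape[2:]
    centre = np.array([0.0, (ny - 1) / 2 * sizes[1], (nx - 1) / 2 * sizes[2]])
    if scenario is not None:
        z_rel = scenario.l2_um - vol.slice_positions_um[0]
        origin = centre + np.array([z_rel, 0, 0])
        direction = np.array([1.0, 0.0, 0.0])
    elif config.plane_axis is not None:
        origin = np.asarray(config.plane_axis[0], dtype=float)
        direction = np.asarray(config.plane_axis[1], dtype=float)
    else:
        z_mid = (vol.slice_positions_um[-1] - vol.slice_positions_um[0]) / 2
        origin = centre + np.array([z_mid, 0, 0])
        direction = np.array([1.0, 0.0, 0.0])
    return place_planes(origin, direction, spacing_um=config.plane_spacing_um,
                        pixel_um=min(sizes[1], sizes[2]))


def measure_hemodynamics(
    vol: Volume4D,
    planes,
    config: RunConfig,
    imported_masks: dict | None = None,
) -> tuple[HemodynamicSeries, dict]:
    """Traces at L1/L3, flow at L2, and the derived pumping observables."""
    l1, l2, l3 = planes
    seg_cfg = SegmentationConfig(**config.segmentation)
    masks = imported_masks or {}

    def _masks_for(label):
        if label in masks:
            return [[m] for m in masks[label]]
        return None

    tr1 = area_trace(vol, l1, seg_cfg, imported_masks=_masks_for("L1"))
    tr3 = area_trace(vol, l3, seg_cfg, imported_masks=_masks_for("L3"))
    g = pressure_gradient(tr1, tr3)
    aa = 0.5 * (tr1.areas_mean_um2 + tr3.areas_mean_um2)
    rn = flow_resistance(aa, closed_flag=tr1.closed_flag & tr3.closed_flag,
                         area_floor_um2=max(4 * l2.pixel_um**2, CLOSURE_AREA_UM2))

    theta = config.theta_deg
    if theta is None:
        theta = vol.meta.get("theta_deg") or 0.0
    theta_rad = np.deg2rad(theta)
    pixel_area = l2.pixel_um**2

    plane_imgs = [extract_plane_image(vol, l2, p) for p in range(vol.phase_count)]
    if seg_cfg.threshold_db is None and "L2" not in masks:
        from dataclasses import replace

        from .lumen_measure import pooled_threshold

        seg_cfg = replace(
            seg_cfg, threshold_db=pooled_threshold([s for s, _ in plane_imgs], seg_cfg)
        )
    v = np.zeros(vol.phase_count)
    a2 = np.zeros(vol.phase_count)
    for p in range(vol.phase_count):
        struct, velo = plane_imgs[p]
        if "L2" in masks:
            mask = masks["L2"][p]
        else:
            reps = segment_lumen(struct, seg_cfg)
            mask = reps[len(reps) // 2]
        a2[p] = mask.sum() * pixel_area
        v[p] = volumetric_flow_rate(velo, mask, theta_rad, pixel_area,
                                    angle_correction=config.angle_correction)

    series = HemodynamicSeries(
        times_s=vol.phase_times_s,
        pressure_gradient=g,
        resistance_norm=rn,
        flow_rate_um3_s=v,
        low_resistance_mask=rn < config.resistance_threshold,
        smoothing_meta={"derivative": "savgol w=5 o=2 circular",
                        "theta_deg": float(theta),
                        "angle_correction": config.angle_correction},
    )
    aux = {"trace_l1": tr1, "trace_l3": tr3, "flow_plane_areas_um2": a2,
           "averaged_area_um2": aa}
    return series, aux


def gated_causality(series: HemodynamicSeries, config: RunConfig):
    """Causality table on the longest contiguous low-resistance window."""
    rn = np.where(np.isfinite(series.pressure_gradient), series.resistance_norm, 1.0)
    _, segments, idx = low_resistance_window(
        rn, threshold=config.resistance_threshold, max_lag=max(config.lags)
    )
    table = causality_table(
        series.pressure_gradient,
        series.flow_rate_um3_s,
        window_idx=idx,
        lags=tuple(config.lags),
        volume_rate_hz=1.0 / float(np.mean(np.diff(series.times_s))),
    )
    return table, segments, idx


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages, persisting every intermediate product.

    Writes ``frames.h5`` (phantom mode), ``volume4d.h5``, ``traces.csv``,
    ``hemodynamics.csv``, ``causality.csv``, ``mechanism.json`` and
    ``summary.json`` under ``outdir``; returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"config": asdict(config)}
    stage = "init"
    try:
        t0 = time.perf_counter()
        scenario = None
        if config.mode == "phantom":
            stage = "phantom"
            scenario = build_scenario(config)
            plan = random_plan(scenario.slice_positions_um,
                               scenario.frames_per_slice, seed=config.seed)
            seqs = acquire(scenario.kinematics, scenario.flow, scenario.optics,
                           plan, theta_deg=scenario.theta_deg,
                           **scenario.render_kwargs)
            if config.save_frames:
                truth = {
                    "radius_field_um": scenario.kinematics.radius_um,
                    "flux_field_um3_s": scenario.flow.flux_um3_s,
                    "kin_z_um": scenario.kinematics.z_um,
                    "kin_t_s": scenario.kinematics.t_s,
                    "start_phases": plan.start_phase_per_slice,
                }
                tio.save_frames_h5(outdir / "frames.h5", seqs, truth=truth)
            log.info("phantom: %d slices rendered in %.1fs",
                     len(seqs), time.perf_counter() - t0)

            stage = "recon"
            t0 = time.perf_counter()
            vol = gate_and_synchronize(seqs, window=tuple(config.kasai_window))
            tio.save_volume_h5(outdir / "volume4d.h5", vol)
            log.info("recon: %d phases x %d slices in %.1fs",
                     vol.phase_count, len(seqs), time.perf_counter() - t0)
        else:
            stage = "import"
            if not config.import_volume_path:
                raise TubepumpError("import mode needs import_volume_path")
            vol = tio.load_volume_h5(config.import_volume_path)

        stage = "measure"
        t0 = time.perf_counter()
        planes = _volume_planes(vol, scenario, config)
        imported = {
            lab: tio.load_mask_stack(p) for lab, p in config.import_mask_paths.items()
        } or None
        series, aux = measure_hemodynamics(vol, planes, config, imported_masks=imported)
        tr1, tr3 = aux["trace_l1"], aux["trace_l3"]
        pd.DataFrame({
            "phase": np.arange(vol.phase_count),
            "time_s": series.times_s,
            "area_L1_mean_um2": tr1.areas_mean_um2,
            "area_L1_std_um2": tr1.areas_std_um2,
            "area_L3_mean_um2": tr3.areas_mean_um2,
            "area_L3_std_um2": tr3.areas_std_um2,
            "area_L2_um2": aux["flow_plane_areas_um2"],
            "closed_L1": tr1.closed_flag,
            "closed_L3": tr3.closed_flag,
        }).to_csv(outdir / "traces.csv", index=False)
        log.info("measure: traces done in %.1fs", time.perf_counter() - t0)

        stage = "mechanics"
        labels = label_phases(tr1, tr3)
        mech = classify_mechanism(series.pressure_gradient, series.flow_rate_um3_s,
                                  labels, series.low_resistance_mask)
        pd.DataFrame({
            "phase": np.arange(vol.phase_count),
            "time_s": series.times_s,
            "G_per_s": series.pressure_gradient,
            "Rnorm": series.resistance_norm,
            "V_um3_per_s": series.flow_rate_um3_s,
            "low_resistance": series.low_resistance_mask,
            "phase_label": labels.labels,
        }).to_csv(outdir / "hemodynamics.csv", index=False)
        (outdir / "mechanism.json").write_text(json.dumps(mech, indent=2))

        stage = "causality"
        causality_error = None
        rows = []
        try:
            table, segments, idx = gated_causality(series, config)
            for r in table:
                rows.append({
                    "direction": r.direction, "lag": r.lag, "lag_ms": r.lag_ms,
                    "F": r.f_stat, "p": r.p_value, "n_effective": r.n_effective,
                    "sig_0.05": 0.05 in r.significant_at,
                    "sig_0.01": 0.01 in r.significant_at,
                })
        except InsufficientDataError as exc:
            causality_error = str(exc)
            idx = np.array([], dtype=int)
        pd.DataFrame(rows, columns=["direction", "lag", "lag_ms", "F", "p",
                                    "n_effective", "sig_0.05", "sig_0.01"]
                     ).to_csv(outdir / "causality.csv", index=False)

        stage = "summary"
        wave_speed = None
        if scenario is not None:
            wave_speed = scenario.extras.get("wave_speed_mm_s")
        flow_report = None
        if wave_speed:
            flow_report = compare_flow_to_wave_speed(
                series.flow_rate_um3_s, aux["flow_plane_areas_um2"], wave_speed,
                min_area_frac=config.peak_speed_min_area_frac,
            )
        sig_cells = [r for r in rows if r["sig_0.05"]]
        summary.update({
            "mode": config.mode,
            "scenario": config.scenario if config.mode == "phantom" else None,
            "phase_count": int(vol.phase_count),
            "period_s": float(vol.period_s),
            "mechanism": mech["tag"],
            "mechanism_report": mech,
            "causality": rows,
            "causality_error": causality_error,
            "n_gated_samples": int(len(idx)),
            "significant_cells": [
                {"direction": r["direction"], "lag": r["lag"], "p": r["p"]}
                for r in sig_cells
            ],
            "flow_vs_wave_speed": flow_report,
        })
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
        return summary
    except TubepumpError:
        summary["failed_stage"] = stage
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
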