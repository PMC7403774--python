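"""Preset phantom scenarios and ground-truth hemodynamic series.

Two study conditions are encoded as ready-made phantoms:

``ventricle_like``
    An actively pumping segment: full open/close cycle with slow
    relaxation and fast contraction, activation travelling at a
    ventricular conduction speed (7 mm/s), and a luminal flow that
    responds to the wall-generated pressure gradient with a 20 ms delay —
    pressure leads flow, the signature of combined suction and pushing.

``outflow_like``
    A passive segment: a fast-opening, slow-closing wall wave travelling
    at only 0.6 mm/s (the outflow-tract conduction range), while the flow
    is an upstream ejection pulse with a peak cross-section-mean speed of
    5.9 mm/s — the flow runs far ahead of the wall wave and is not caused
    by the local wall motion.

``truth_hemodynamics`` evaluates the pumping observables directly from
the ground-truth kinematics and flux (bypassing rendering and
segmentation), adding measurement-like noise; it is the fast path for
seed-replicated statistical checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .frames import OpticsConfig
from .lumen_measure import CLOSURE_AREA_UM2, LumenTrace
from .mechanics import (
    HemodynamicSeries,
    flow_resistance,
    pressure_gradient,
    smooth_derivative,
)
from .phantom import (
    CLOSED_RADIUS_UM,
    GroundTruthFlow,
    WallKinematics,
    consistent_inlet_flux,
    derive_flow,
    make_wall_kinematics,
    roughen_kinematics,
)

#: legacy resistance floor (um^2): 4 pixels at a 2 um pitch
DEFAULT_AREA_FLOOR_UM2 = 16.0


@dataclass
class Scenario:
    """A fully specified phantom study condition."""

    name: str
    kinematics: WallKinematics
    flow: GroundTruthFlow
    optics: OpticsConfig
    theta_deg: float
    l1_um: float
    l2_um: float
    l3_um: float
    slice_positions_um: np.ndarray
    frames_per_slice: int
    target_peak_speed_mm_s: float
    render_kwargs: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    @property
    def phase_count(self) -> int:
        return int(round(self.kinematics.period_s * self.optics.b_scan_rate_hz))

    @property
    def pixel_area_um2(self) -> float:
        return self.optics.axial_pixel_um * self.optics.lateral_pixel_um


def _station_area_series(kin: WallKinematics, z_um: float, t: np.ndarray) -> np.ndarray:
    r = kin.radius_fn(np.asarray(z_um, dtype=float), t)
    return np.pi * np.asarray(r) ** 2


def _truth_pressure_gradient(
    kin: WallKinematics, l1_um: float, l3_um: float, t: np.ndarray
) -> np.ndarray:
    """Noise-free G(t) on an arbitrary time grid; 0 where either plane closed."""
    dt = float(t[1] - t[0])
    a1 = _station_area_series(kin, l1_um, t)
    a3 = _station_area_series(kin, l3_um, t)
    d1 = smooth_derivative(a1, dt)
    d3 = smooth_derivative(a3, dt)
    a_closed = np.pi * CLOSED_RADIUS_UM**2
    g = np.zeros_like(a1)
    open_ = (a1 > a_closed) & (a3 > a_closed)
    g[open_] = -d1[open_] / a1[open_] + d3[open_] / a3[open_]
    return g


def ventricle_like(
    period_s: float = 0.5,
    base_radius_um: float = 40.0,
    wave_speed_mm_s: float = 7.0,
    axis_length_um: float = 190.0,
    n_slices: int = 20,
    frames_per_slice: int = 200,
    theta_deg: float = 60.0,
    pressure_to_flow_lag_s: float = 0.02,
    target_peak_speed_mm_s: float = 4.9,
    snr_db: float = 30.0,
    drive_seed: int = 0,
    nuisance_flow_frac: float = 0.3,
    wall_roughness_frac: float = 0.05,
    wall_roughness_tcorr_s: float = 0.03,
) -> Scenario:
    """Actively pumping ventricle-like phantom: pressure leads flow by 20 ms.

    The luminal flow is the lagged response to the wall-generated
    pressure gradient plus a seeded smooth nuisance component
    (``nuisance_flow_frac`` of the response's in-window spread) standing
    in for flow sources the local two-plane pressure proxy cannot see —
    upstream chambers, secondary flows. Without it the flow would be a
    deterministic function of the gradient, which no measured flow is.
    """
    optics = OpticsConfig(snr_db=snr_db, axial_pixel_um=1.0, lateral_pixel_um=1.0)
    kin = make_wall_kinematics(
        "suction",
        period_s=period_s,
        base_radius_um=base_radius_um,
        amplitude_um=base_radius_um,  # closes fully
        wave_speed_mm_s=wave_speed_mm_s,
        axis_length_um=axis_length_um,
        taper=0.3,
        n_z=96,
        n_t=256,
    )
    if wall_roughness_frac > 0:
        kin = roughen_kinematics(kin, seed=drive_seed, amp_frac=wall_roughness_frac,
                                 t_corr_s=wall_roughness_tcorr_s)
    # planes sit on acquisition slice stations (no inter-slice blending)
    step = axis_length_um / (n_slices - 1)
    l2 = step * round(axis_length_um / 2.0 / step)
    l1, l3 = l2 - 30.0, l2 + 30.0

    t = kin.t_s
    # the flow responds to the band-limited pressure gradient: build G on
    # the reconstruction phase grid (volume-rate sampling + the same
    # smoothed derivative the measurement uses), then upsample — flow
    # inertia low-passes the response, and this keeps the drive linear in
    # the *observable* gradient
    phase_count = int(round(period_s * optics.b_scan_rate_hz))
    t50 = np.arange(phase_count) / optics.b_scan_rate_hz
    g50 = _truth_pressure_gradient(kin, l1, l3, t50)
    g0 = np.interp(t, np.concatenate([t50, [period_s]]),
                   np.concatenate([g50, [g50[0]]]))
    lag_samples = int(round(pressure_to_flow_lag_s / (period_s / len(t))))
    g_del = np.roll(g0, lag_samples)

    a2 = _station_area_series(kin, l2, t)
    # suppress the flow response while the lumen is not reliably open (the
    # near-closure pressure spikes act against a dominating resistance);
    # above the knee — the same 25%-of-max gate the peak-speed report
    # uses — the pressure-to-flow gain is flat
    taper_w = np.clip(a2 / (0.15 * a2.max()), 0.0, 1.0) ** 3
    raw = g_del * taper_w

    # the drive only applies while the whole tube is open (otherwise the
    # closed plug dictates the flux); the peak mean speed is calibrated
    # over the reliably open phases
    fully_open = np.all(kin.radius_um > CLOSED_RADIUS_UM, axis=0)
    gate = fully_open & (a2 >= 0.25 * a2.max())
    speed_raw = np.zeros_like(raw)
    speed_raw[gate] = raw[gate] / a2[gate]
    kappa = target_peak_speed_mm_s * 1e3 / max(np.max(np.abs(speed_raw)), 1e-300)
    v_target = kappa * raw  # um^3/s at L2
    if nuisance_flow_frac > 0:
        rng = np.random.default_rng(drive_seed)
        smooth = gaussian_filter1d(rng.standard_normal(len(t)), 10.0, mode="wrap")
        smooth /= max(np.std(smooth[fully_open]), 1e-300)
        amp = nuisance_flow_frac * np.std(v_target[fully_open])
        v_target = v_target + amp * smooth * taper_w
    # one rescale so the realized in-gate peak (response + nuisance) sits
    # on the target speed; the gate is the reliably-open window the
    # peak-speed measurement uses
    gate_cal = a2 >= 0.25 * a2.max()
    speed_cal = np.zeros_like(v_target)
    speed_cal[gate_cal] = v_target[gate_cal] / a2[gate_cal]
    peak = np.max(np.abs(speed_cal))
    if peak > 0:
        v_target = v_target * (target_peak_speed_mm_s * 1e3 / peak)

    inlet = consistent_inlet_flux(kin, drive_um3_s=v_target, drive_station_um=l2)
    flow = derive_flow(kin, inlet, profile="poiseuille")

    return Scenario(
        name="ventricle_like",
        kinematics=kin,
        flow=flow,
        optics=optics,
        theta_deg=theta_deg,
        l1_um=l1,
        l2_um=l2,
        l3_um=l3,
        slice_positions_um=np.arange(n_slices) * step,
        frames_per_slice=frames_per_slice,
        target_peak_speed_mm_s=target_peak_speed_mm_s,
        render_kwargs={"image_shape": (128, 128)},
        extras={"pressure_to_flow_lag_s": pressure_to_flow_lag_s,
                "wave_speed_mm_s": wave_speed_mm_s},
    )


def outflow_like(
    period_s: float = 0.5,
    base_radius_um: float = 25.0,
    wave_speed_mm_s: float = 0.6,
    axis_length_um: float = 190.0,
    n_slices: int = 20,
    frames_per_slice: int = 200,
    theta_deg: float = 60.0,
    target_peak_speed_mm_s: float = 5.9,
    snr_db: float = 30.0,
    drive_seed: int = 0,
    wall_roughness_frac: float = 0.05,
    wall_roughness_tcorr_s: float = 0.03,
) -> Scenario:
    """Passive outflow-tract-like phantom: slow wall wave, fast ejection flow."""
    optics = OpticsConfig(snr_db=snr_db, axial_pixel_um=1.0, lateral_pixel_um=1.0)
    kin = make_wall_kinematics(
        "passive_wave",
        period_s=period_s,
        base_radius_um=base_radius_um,
        amplitude_um=base_radius_um,
        wave_speed_mm_s=wave_speed_mm_s,
        axis_length_um=axis_length_um,
        n_z=96,
        n_t=256,
    )
    if wall_roughness_frac > 0:
        kin = roughen_kinematics(kin, seed=drive_seed, amp_frac=wall_roughness_frac,
                                 t_corr_s=wall_roughness_tcorr_s)
    # planes sit on acquisition slice stations (no inter-slice blending)
    step = axis_length_um / (n_slices - 1)
    l2 = step * round(axis_length_um / 2.0 / step)
    l1, l3 = l2 - 30.0, l2 + 30.0

    # ejection pulse centred in the fully open part of the cycle
    t = kin.t_s
    fully_open = np.all(kin.radius_um > CLOSED_RADIUS_UM, axis=0)
    if not fully_open.any():
        raise ValueError("outflow phantom never fully open; lengthen the cycle")
    # longest circular open run
    idx = np.nonzero(fully_open)[0]
    gaps = np.nonzero(np.diff(idx) > 1)[0]
    if len(gaps):
        idx = np.roll(idx, -(gaps[0] + 1))
    centre_t = t[idx[len(idx) // 2]]
    width = max(len(idx), 4) / len(t) * period_s
    phase_dist = np.minimum(np.abs(t - centre_t), period_s - np.abs(t - centre_t))
    pulse = np.exp(-0.5 * (phase_dist / (0.25 * width)) ** 2)

    a2 = _station_area_series(kin, l2, t)
    # fixed-point calibration of the pulse amplitude: the flux at L2 is the
    # drive plus a drive-independent wall term, so one or two rescales land
    # the in-window peak mean speed on target
    q_pk = target_peak_speed_mm_s * 1e3 * a2.max()
    flow = None
    for _ in range(3):
        drive = q_pk * pulse
        inlet = consistent_inlet_flux(kin, drive_um3_s=drive, drive_station_um=l2)
        flow = derive_flow(kin, inlet, profile="plug")
        # peak evaluated over the reliably open gate, matching the
        # peak-speed measurement definition
        q2 = flow.flux_at(l2, t)
        gate_cal = a2 >= 0.25 * a2.max()
        speed = np.zeros_like(q2)
        speed[gate_cal] = q2[gate_cal] / a2[gate_cal] * 1e-3  # mm/s
        peak = np.max(np.abs(speed))
        if abs(peak - target_peak_speed_mm_s) < 1e-3 * target_peak_speed_mm_s:
            break
        q_pk *= target_peak_speed_mm_s / peak

    return Scenario(
        name="outflow_like",
        kinematics=kin,
        flow=flow,
        optics=optics,
        theta_deg=theta_deg,
        l1_um=l1,
        l2_um=l2,
        l3_um=l3,
        slice_positions_um=np.arange(n_slices) * step,
        frames_per_slice=frames_per_slice,
        target_peak_speed_mm_s=target_peak_speed_mm_s,
        render_kwargs={"image_shape": (128, 128)},
        extras={"wave_speed_mm_s": wave_speed_mm_s},
    )


def _pseudo_trace(label: str, times: np.ndarray, areas: np.ndarray,
                  pixel_area_um2: float = 1.0) -> LumenTrace:
    closed = areas < max(4 * pixel_area_um2, CLOSURE_AREA_UM2)
    return LumenTrace(
        plane_label=label,
        times_s=times,
        areas_mean_um2=np.maximum(areas, 0.0),
        areas_std_um2=np.zeros_like(areas),
        replicates_um2=np.maximum(areas, 0.0)[:, None],
        closed_flag=closed,
        pixel_area_um2=pixel_area_um2,
    )


def truth_hemodynamics(
    scenario: Scenario,
    seed: int,
    area_noise_frac: float = 0.003,
    flow_noise_frac: float = 0.05,
    resistance_threshold: float = 0.1,
) -> tuple[HemodynamicSeries, LumenTrace, LumenTrace]:
    """Pumping observables from ground truth plus measurement-like noise.

    Areas at L1/L3 and the flux at L2 are read off the phantom's exact
    kinematics and flow on the reconstruction phase grid, then perturbed
    by i.i.d. Gaussian noise — a fraction of each series' peak matching
    what the imaging pipeline delivers (sub-percent area jitter from
    cycle-compounded segmentation; a few percent on the Doppler-
    integrated flow). Used for seed-replicated statistical checks where
    rendering every replicate would add nothing.
    """
    rng = np.random.default_rng(seed)
    kin = scenario.kinematics
    pc = scenario.phase_count
    times = np.arange(pc) / scenario.optics.b_scan_rate_hz

    a1 = _station_area_series(kin, scenario.l1_um, times)
    a3 = _station_area_series(kin, scenario.l3_um, times)
    a1n = np.maximum(a1 + rng.normal(0, area_noise_frac * a1.max(), pc), 0.0)
    a3n = np.maximum(a3 + rng.normal(0, area_noise_frac * a3.max(), pc), 0.0)
    # keep truly closed phases closed: noise must not reopen the lumen
    closed_floor = max(4 * scenario.pixel_area_um2, CLOSURE_AREA_UM2)
    a1n[a1 < closed_floor] = a1[a1 < closed_floor]
    a3n[a3 < closed_floor] = a3[a3 < closed_floor]
    tr1 = _pseudo_trace("L1", times, a1n, scenario.pixel_area_um2)
    tr3 = _pseudo_trace("L3", times, a3n, scenario.pixel_area_um2)

    g = pressure_gradient(tr1, tr3)
    aa = 0.5 * (tr1.areas_mean_um2 + tr3.areas_mean_um2)
    rn = flow_resistance(aa, closed_flag=tr1.closed_flag & tr3.closed_flag,
                         area_floor_um2=max(4 * scenario.pixel_area_um2, CLOSURE_AREA_UM2))
    v = scenario.flow.flux_at(scenario.l2_um, times)
    v = v + rng.normal(0, flow_noise_frac * np.max(np.abs(v)), pc)

    series = HemodynamicSeries(
        times_s=times,
        pressure_gradient=g,
        resistance_norm=rn,
        flow_rate_um3_s=v,
        low_resistance_mask=rn < resistance_threshold,
        smoothing_meta={"derivative": "savgol w=5 o=2 circular",
                        "area_noise_frac": area_noise_frac,
                        "flow_noise_frac": flow_noise_frac},
    )
    return series, tr1, tr3
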