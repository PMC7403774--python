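"""Wall kinematics, mass-conserving flow, and B-scan rendering."""

import numpy as np
import pytest

from tubepump.errors import InvalidConfigurationError, OcclusionInconsistencyError
from tubepump.frames import OpticsConfig
from tubepump.phantom import (
    CLOSED_RADIUS_UM,
    consistent_inlet_flux,
    derive_flow,
    make_wall_kinematics,
    render_bscan_sequence,
    roughen_kinematics,
)


@pytest.mark.parametrize("mechanism", ["peristaltic", "suction", "passive_wave"])
def test_kinematics_periodic_and_nonnegative(mechanism):
    kin = make_wall_kinematics(mechanism, period_s=0.5, base_radius_um=30,
                               amplitude_um=20, wave_speed_mm_s=1.0,
                               axis_length_um=300, n_z=32, n_t=64)
    assert np.all(kin.radius_um >= 0)
    r0 = kin.radius_fn(kin.z_um[:, None], np.array([[0.0]]))
    rT = kin.radius_fn(kin.z_um[:, None], np.array([[kin.period_s]]))
    assert np.max(np.abs(r0 - rT)) < 1e-9


def test_zero_amplitude_is_static():
    kin = make_wall_kinematics("peristaltic", period_s=0.5, base_radius_um=30,
                               amplitude_um=0.0, wave_speed_mm_s=1.0)
    assert np.ptp(kin.radius_um) == 0


def test_invalid_configuration_rejected():
    with pytest.raises(InvalidConfigurationError):
        make_wall_kinematics("peristaltic", period_s=-1, base_radius_um=30, amplitude_um=5)
    with pytest.raises(InvalidConfigurationError):
        make_wall_kinematics("peristaltic", period_s=0.5, base_radius_um=5, amplitude_um=30)
    with pytest.raises(InvalidConfigurationError):
        make_wall_kinematics("nope", period_s=0.5, base_radius_um=30, amplitude_um=5)


def test_peristaltic_constriction_travels_at_wave_speed():
    # c = 1 mm/s: the constriction minimum at z recurs delayed by z/c
    kin = make_wall_kinematics("peristaltic", period_s=0.5, base_radius_um=40,
                               amplitude_um=20, wave_speed_mm_s=1.0,
                               axis_length_um=500)
    t = np.linspace(0, 0.5, 2000, endpoint=False)
    t_min_0 = t[np.argmin(kin.radius_fn(np.asarray(0.0), t))]
    t_min_250 = t[np.argmin(kin.radius_fn(np.asarray(250.0), t))]
    delay = (t_min_250 - t_min_0) % 0.5
    assert delay == pytest.approx(0.25, abs=2e-3)  # 250 um / (1 mm/s)


def test_mass_conservation_residual_on_200_grid():
    """Staggered-form conservation residual below 1% of max |dA/dt|."""
    kin = make_wall_kinematics("peristaltic", period_s=0.5, base_radius_um=40,
                               amplitude_um=20, wave_speed_mm_s=1.0,
                               axis_length_um=500, n_z=200, n_t=200)
    fl = derive_flow(kin, 0.0, profile="plug")
    dz = np.diff(kin.z_um)[:, None]
    dq_dz = (fl.flux_um3_s[1:] - fl.flux_um3_s[:-1]) / dz
    da_mid = 0.5 * (fl.dA_dt_um2_s[1:] + fl.dA_dt_um2_s[:-1])
    residual = np.abs(da_mid + dq_dz)
    assert residual.max() < 0.01 * np.abs(fl.dA_dt_um2_s).max()


def test_static_tube_carries_inlet_flux_unchanged():
    kin = make_wall_kinematics("peristaltic", period_s=0.5, base_radius_um=30,
                               amplitude_um=0.0, wave_speed_mm_s=1.0, n_z=40)
    fl = derive_flow(kin, 123.0, profile="plug")
    assert np.allclose(fl.flux_um3_s, 123.0)


def test_uniform_wall_motion_closed_form_flux():
    # z-uniform pulsation: Q(L, t) = -L * dA/dt with zero inlet flux
    kin = make_wall_kinematics(
        "suction", period_s=1.0, base_radius_um=30, amplitude_um=10,
        wave_speed_mm_s=1e6, axis_length_um=200, n_z=80, n_t=128,
        profile_fn=lambda u: 0.5 + 0.5 * np.sin(2 * np.pi * u),
    )
    fl = derive_flow(kin, 0.0, profile="plug")
    L = kin.z_um[-1]
    expected = -L * fl.dA_dt_um2_s[-1]
    scale = np.abs(expected).max()
    assert np.max(np.abs(fl.flux_um3_s[-1] - expected)) < 0.01 * scale


def test_peristalsis_transports_net_volume_forward():
    kin = make_wall_kinematics("peristaltic", period_s=0.5, base_radius_um=40,
                               amplitude_um=25, wave_speed_mm_s=1.0,
                               axis_length_um=500, n_z=150, n_t=300)
    fl = derive_flow(kin, 0.0, profile="plug")
    assert fl.flux_um3_s[75].mean() > 0


def test_occluded_lumen_with_flux_raises():
    kin = make_wall_kinematics("suction", period_s=0.5, base_radius_um=30,
                               amplitude_um=30, wave_speed_mm_s=7.0,
                               axis_length_um=200, n_z=48, n_t=128)
    with pytest.raises(OcclusionInconsistencyError):
        derive_flow(kin, 1e5, profile="plug")
    # the consistent inlet makes the same kinematics admissible
    inlet = consistent_inlet_flux(kin, 0.0)
    fl = derive_flow(kin, inlet, profile="plug")
    closed = kin.radius_um <= CLOSED_RADIUS_UM
    assert np.abs(fl.flux_um3_s[closed]).max() < 1e-3 * np.abs(fl.flux_um3_s).max() + 1e-9


def test_poiseuille_centerline_is_twice_mean(vent_scenario):
    fl = vent_scenario.flow
    t = 0.3
    z = vent_scenario.l2_um
    centre = fl.tube_velocity_mm_s(z, np.array([0.0]), t)[0]
    r = float(vent_scenario.kinematics.radius_fn(np.asarray(z), np.asarray(t)))
    q = float(fl.flux_at(z, np.asarray([t]))[0])
    mean = q / (np.pi * r**2) * 1e-3
    assert centre == pytest.approx(2 * mean, rel=1e-6)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _conj_phase(frames, mask):
    prod = frames[:, :, 1:] * np.conj(frames[:, :, :-1])
    sel = mask[:, 1:] & mask[:, :-1]
    return np.angle(np.sum(prod[:, sel]))


def test_render_static_zero_flow_has_zero_phase(optics):
    seq = render_bscan_sequence(None, None, optics, 0.0, n_frames=30, seed=1,
                                static_radius_um=25.0, uniform_axial_velocity_mm_s=0.0)
    yy, xx = np.mgrid[0:64, 0:64]
    lumen = np.hypot((yy - 31.5) * 2, (xx - 31.5) * 2) < 20
    phase = _conj_phase(seq.frames, lumen)
    assert abs(phase) < 0.05


def test_render_imposed_quarter_pi_phase_roundtrip(optics):
    """Independent single-pixel oracle: arg of the summed conjugate product."""
    v = optics.velocity_per_radian_mm_s * np.pi / 2  # 4.92 mm/s
    seq = render_bscan_sequence(None, None, optics, 0.0, n_frames=60, seed=2,
                                static_radius_um=25.0, uniform_axial_velocity_mm_s=v)
    yy, xx = np.mgrid[0:64, 0:64]
    lumen = np.hypot((yy - 31.5) * 2, (xx - 31.5) * 2) < 18
    phase = _conj_phase(seq.frames, lumen)
    assert phase == pytest.approx(np.pi / 2, rel=0.02)


def test_render_determinism(optics, vent_scenario):
    kw = dict(n_frames=10, seed=42, theta_deg=60.0)
    a = render_bscan_sequence(vent_scenario.kinematics, vent_scenario.flow,
                              optics, vent_scenario.l2_um, **kw)
    b = render_bscan_sequence(vent_scenario.kinematics, vent_scenario.flow,
                              optics, vent_scenario.l2_um, **kw)
    assert np.array_equal(a.frames, b.frames)


def test_render_aliasing_recorded(optics):
    v_over = 1.1 * optics.nyquist_velocity_mm_s
    seq = render_bscan_sequence(None, None, optics, 0.0, n_frames=5, seed=0,
                                static_radius_um=25.0,
                                uniform_axial_velocity_mm_s=v_over)
    assert "doppler_aliasing" in seq.meta["warnings"]


def test_render_outside_tube_rejected(optics, vent_scenario):
    with pytest.raises(InvalidConfigurationError):
        render_bscan_sequence(vent_scenario.kinematics, vent_scenario.flow,
                              optics, 1e6, n_frames=5, seed=0)


def test_start_phase_offset_shifts_frame_content(optics):
    """Same seed, frozen speckle: slices at phases 0.0 / 0.4 match after offset."""
    kin = make_wall_kinematics("suction", period_s=0.5, base_radius_um=30,
                               amplitude_um=12, wave_speed_mm_s=1e6,
                               axis_length_um=100, n_t=128)
    kw = dict(n_frames=120, seed=7, theta_deg=0.0, speckle_tau_frames=None,
              blood_tau_frames=None)
    a = render_bscan_sequence(kin, None, optics, 50.0, start_phase=0.0, **kw)
    b = render_bscan_sequence(kin, None, optics, 50.0, start_phase=0.4, **kw)
    offset = int(round(0.4 * 0.5 * optics.b_scan_rate_hz))  # 0.4 T in frames
    ia = np.abs(a.frames[offset:60 + offset]).ravel()
    ib = np.abs(b.frames[:60]).ravel()
    corr = np.corrcoef(ia, ib)[0, 1]
    assert corr > 0.95


def test_roughen_preserves_closure_and_period():
    kin = make_wall_kinematics("suction", period_s=0.5, base_radius_um=30,
                               amplitude_um=30, wave_speed_mm_s=7.0,
                               axis_length_um=190, n_z=48, n_t=128)
    rough = roughen_kinematics(kin, seed=3, amp_frac=0.05)
    closed = kin.radius_um <= CLOSED_RADIUS_UM
    assert np.all(rough.radius_um[closed] <= CLOSED_RADIUS_UM * 1.1)
    r0 = rough.radius_fn(rough.z_um[:, None], np.array([[0.0]]))
    rT = rough.radius_fn(rough.z_um[:, None], np.array([[0.5]]))
    assert np.max(np.abs(r0 - rT)) < 1e-6
    open_ = ~closed
    rel = np.abs(rough.radius_um[open_] / kin.radius_um[open_] - 1.0)
    assert 0.0 < rel.max() < 0.3


def test_optics_validation():
    with pytest.raises(InvalidConfigurationError):
        OpticsConfig(wavelength_m=-1)
    o = OpticsConfig()
    assert o.nyquist_velocity_mm_s == pytest.approx(9.8357, rel=1e-3)
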