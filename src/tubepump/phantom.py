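"""Ground-truthed synthetic beating-tube phantom.

The phantom emulates a short segment of a valveless embryonic heart tube:
an axisymmetric lumen whose radius ``r(z, t)`` varies periodically along
the tube axis ``z``, an incompressible luminal flow consistent with the
wall motion, and complex OCT-like B-scan sequences whose inter-A-scan
phase encodes the axial (beam-projected) blood velocity. Every quantity a
downstream stage estimates — radius, flux, velocity, cycle phase — exists
here as exact ground truth.

Units: lengths in micrometres, time in seconds, velocities in mm/s and
volume flux in um^3/s.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidConfigurationError, OcclusionInconsistencyError
from .frames import ComplexFrameSequence, OpticsConfig

MECHANISMS = ("peristaltic", "suction", "passive_wave")

#: lumen radius (um) below which the cross-section counts as closed
CLOSED_RADIUS_UM = 0.5


# ---------------------------------------------------------------------------
# wall kinematics
# ---------------------------------------------------------------------------

def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _piecewise_cycle(u: np.ndarray, knots: Sequence[tuple[float, float, float]]) -> np.ndarray:
    """Periodic open-fraction profile from (start, stop, delta) ramps.

    ``knots`` lists smoothstep ramps; between ramps the profile holds the
    last value; each ramp changes the level by ``delta`` (any sign/size).
    """
    u = np.asarray(u, dtype=float) % 1.0
    out = np.zeros_like(u)
    level = 0.0
    prev_stop = 0.0
    for start, stop, direction in knots:
        hold = (u >= prev_stop) & (u < start)
        out[hold] = level
        seg = (u >= start) & (u < stop)
        s = _smoothstep((u[seg] - start) / (stop - start))
        out[seg] = level + direction * s
        level = level + direction
        prev_stop = stop
    out[u >= prev_stop] = level
    return out


def ventricle_open_fraction(u: np.ndarray) -> np.ndarray:
    """Ventricle-like cycle at the upstream end of the segment.

    Closed, then a relaxation ramp (0.35 of the cycle — much longer than
    the 0.18 contraction ramp, mirroring the slow-filling / fast-ejection
    asymmetry of early embryonic ventricles) to an early area peak,
    followed by a gentle decline while downstream stations are still
    filling, then fast contraction.
    """
    return _piecewise_cycle(
        u, [(0.10, 0.45, +1.0), (0.45, 0.72, -0.15), (0.72, 0.86, -0.85)]
    )


def ventricle_open_fraction_slow(u: np.ndarray) -> np.ndarray:
    """Downstream variant of the ventricle cycle: slower area-change rate.

    Same closed interval but a longer relaxation with a brief rapid-
    filling surge mid-cycle and a peak late in the open phase, matching
    the downstream end of an actively pumping segment. Blending this with
    :func:`ventricle_open_fraction` along the axis gives stations whose
    dynamics differ in *shape*, not merely timing; the filling surge puts
    a sharp pressure-gradient transient inside the open (low-resistance)
    part of the cycle.
    """
    return _piecewise_cycle(
        u,
        [(0.10, 0.48, +0.55), (0.48, 0.56, +0.35), (0.56, 0.64, +0.10),
         (0.74, 0.92, -1.0)],
    )


def ventricle_morph_profile(u: np.ndarray, z_frac: np.ndarray = 0.0,
                            strength: float = 0.7) -> np.ndarray:
    """Axially morphing ventricle cycle: upstream fast, downstream slow."""
    m = strength * np.asarray(z_frac, dtype=float)
    return (1.0 - m) * ventricle_open_fraction(u) + m * ventricle_open_fraction_slow(u)


def outflow_open_fraction(u: np.ndarray) -> np.ndarray:
    """Outflow-tract-like cycle: fast opening, long plateau decay, slow closing."""
    return _piecewise_cycle(u, [(0.05, 0.20, +1.0), (0.45, 0.95, -1.0)])


def roughen_kinematics(
    kin: WallKinematics,
    seed: int,
    amp_frac: float = 0.025,
    t_corr_s: float = 0.02,
    z_corr_um: float = 20.0,
) -> WallKinematics:
    """Superimpose band-limited wall-motion irregularity on a kinematics.

    Real endocardial area traces are not smooth ramps: trabeculation,
    out-of-plane motion and beat-to-beat irregularity wrinkle them at the
    sampling scale. This multiplies the radius by ``1 + w(z, t)`` with
    ``w`` a seeded Gaussian field, periodic in t, with the given
    correlation scales and relative amplitude. Closed phases stay closed.
    """
    rng = np.random.default_rng(seed)
    n_t = 256
    n_zk = max(int(np.ceil((kin.z_um[-1] - kin.z_um[0]) / z_corr_um)) * 2 + 1, 5)
    zk = np.linspace(kin.z_um[0], kin.z_um[-1], n_zk)
    dt = kin.period_s / n_t
    w = rng.standard_normal((n_zk, n_t))
    w = gaussian_filter(w, (1.0, t_corr_s / dt), mode=("nearest", "wrap"))
    w *= amp_frac / w.std()
    tk = np.arange(n_t) * dt

    base_fn = kin.radius_fn

    def radius_fn(z, t):
        z_arr = np.asarray(z, dtype=float)
        t_arr = np.asarray(t, dtype=float)
        r = base_fn(z_arr, t_arr)
        zb, tb = np.broadcast_arrays(z_arr, t_arr)
        zi = np.clip((zb - zk[0]) / (zk[-1] - zk[0]) * (n_zk - 1), 0, n_zk - 1)
        ti = (tb / dt) % n_t
        from scipy.ndimage import map_coordinates

        wig = map_coordinates(w, [np.atleast_1d(zi).ravel(), np.atleast_1d(ti).ravel()],
                              order=1, mode="grid-wrap").reshape(np.shape(zb))
        return np.maximum(r * (1.0 + wig), 0.0)

    radius = radius_fn(kin.z_um[:, None], kin.t_s[None, :])
    return WallKinematics(
        z_um=kin.z_um,
        t_s=kin.t_s,
        radius_um=radius,
        period_s=kin.period_s,
        mechanism_tag=kin.mechanism_tag,
        wave_speed_mm_s=kin.wave_speed_mm_s,
        base_radius_um=kin.base_radius_um,
        amplitude_um=kin.amplitude_um,
        radius_fn=radius_fn,
    )


def _travelling_bump(u: np.ndarray, kappa: float = 12.0) -> np.ndarray:
    """Smooth periodic constriction bump, max 1 at u=0.5, near 0 elsewhere."""
    u = np.asarray(u, dtype=float)
    return np.exp(kappa * (np.cos(2.0 * np.pi * (u - 0.5)) - 1.0))


@dataclass
class WallKinematics:
    """Periodic lumen-radius field r(z, t) of the tube wall.

    ``radius_fn(z, t)`` evaluates the radius at arbitrary axial position
    and time; ``radius`` caches it on the stored ``(z, t)`` grid.
    """

    z_um: np.ndarray
    t_s: np.ndarray
    radius_um: np.ndarray  # (n_z, n_t)
    period_s: float
    mechanism_tag: str
    wave_speed_mm_s: float
    base_radius_um: float
    amplitude_um: float
    radius_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] = field(repr=False, default=None)

    @property
    def area_um2(self) -> np.ndarray:
        """Luminal cross-section area pi r^2 on the (z, t) grid."""
        return np.pi * self.radius_um**2

    def area_at(self, z_um: float, t_s: np.ndarray) -> np.ndarray:
        r = self.radius_fn(np.asarray(z_um, dtype=float), np.asarray(t_s, dtype=float))
        return np.pi * r**2


def make_wall_kinematics(
    mechanism: str,
    period_s: float,
    base_radius_um: float,
    amplitude_um: float,
    wave_speed_mm_s: float = 7.0,
    axis_length_um: float = 200.0,
    n_z: int = 64,
    n_t: int = 256,
    taper: float = 0.0,
    profile_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> WallKinematics:
    """Build a periodic radius field for one of the pumping mechanisms.

    peristaltic
        Travelling constriction ``r = r0 - dr * g((t - z/c) mod T)``.
    suction
        Ventricle-like open/close cycle whose activation travels at the
        conduction speed ``c``, so upstream stations lead downstream ones;
        ``taper`` linearly reduces the open radius towards the outlet.
    passive_wave
        Outflow-tract-like fast-open / slow-close wave travelling at a
        slow wave speed (the wave is a passive response, intended to be
        slower than the flow it coexists with).
    """
    if mechanism not in MECHANISMS:
        raise InvalidConfigurationError(f"unknown mechanism {mechanism!r}")
    if period_s <= 0:
        raise InvalidConfigurationError("period must be positive")
    if base_radius_um <= 0 or amplitude_um < 0 or base_radius_um < amplitude_um:
        raise InvalidConfigurationError("need base_radius > 0 and base_radius >= amplitude >= 0")
    if mechanism in ("peristaltic", "passive_wave") and wave_speed_mm_s <= 0:
        raise InvalidConfigurationError("travelling mechanisms need wave_speed > 0")
    if mechanism == "suction" and wave_speed_mm_s <= 0:
        raise InvalidConfigurationError("conduction speed must be positive")

    c_um_s = wave_speed_mm_s * 1e3  # mm/s -> um/s

    if profile_fn is None:
        if mechanism == "peristaltic":
            profile_fn = _travelling_bump
        elif mechanism == "suction":
            profile_fn = ventricle_morph_profile
        else:
            profile_fn = outflow_open_fraction

    # profiles may depend on the axial position (shape morphing along z)
    _takes_z_frac = "z_frac" in inspect.signature(profile_fn).parameters

    def radius_fn(z, t):
        z = np.asarray(z, dtype=float)
        t = np.asarray(t, dtype=float)
        u = ((t - z / c_um_s) / period_s) % 1.0
        if _takes_z_frac:
            f = profile_fn(u, z / max(axis_length_um, 1e-9))
        else:
            f = profile_fn(u)
        if mechanism == "peristaltic":
            r = base_radius_um - amplitude_um * f
        else:
            rest = base_radius_um - amplitude_um
            scale = 1.0 - taper * z / max(axis_length_um, 1e-9)
            r = rest + amplitude_um * f * scale
        return np.maximum(r, 0.0)

    z = np.linspace(0.0, axis_length_um, n_z)
    t = np.arange(n_t) / n_t * period_s
    radius = radius_fn(z[:, None], t[None, :])
    return WallKinematics(
        z_um=z,
        t_s=t,
        radius_um=radius,
        period_s=period_s,
        mechanism_tag=mechanism,
        wave_speed_mm_s=wave_speed_mm_s,
        base_radius_um=base_radius_um,
        amplitude_um=amplitude_um,
        radius_fn=radius_fn,
    )


# ---------------------------------------------------------------------------
# mass-conserving flow
# ---------------------------------------------------------------------------

def _periodic_time_derivative(f: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference d/dt along the last axis with periodic wrap."""
    return (np.roll(f, -1, axis=-1) - np.roll(f, 1, axis=-1)) / (2.0 * dt)


def _wall_cumflux(kin: WallKinematics, oversample: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """(cumulative wall flux, dA/dt) on the kinematics grid.

    ``cum[i, j] = int_{z0}^{z_i} dA/dt dz'`` evaluated by trapezoid on a
    z-grid refined ``oversample``-fold from the analytic radius field, so
    the discretization error of the flux integral stays well below the
    central-difference error of the conservation check itself.
    """
    n_t = len(kin.t_s)
    dt = kin.period_s / n_t
    n_z = len(kin.z_um)
    fine = np.interp(
        np.arange((n_z - 1) * oversample + 1) / oversample,
        np.arange(n_z),
        kin.z_um,
    )
    area_f = np.pi * kin.radius_fn(fine[:, None], kin.t_s[None, :]) ** 2
    dA_f = _periodic_time_derivative(area_f, dt)
    dz_f = np.diff(fine)
    seg = 0.5 * (dA_f[1:] + dA_f[:-1]) * dz_f[:, None]
    cum_f = np.vstack([np.zeros((1, n_t)), np.cumsum(seg, axis=0)])
    return cum_f[::oversample], dA_f[::oversample]


@dataclass
class GroundTruthFlow:
    """Incompressible flow field consistent with a :class:`WallKinematics`.

    ``flux_um3_s`` is the volume flux Q(z, t) through each cross section;
    positive flux points towards +z (the forward-flow direction).
    """

    kinematics: WallKinematics
    flux_um3_s: np.ndarray  # (n_z, n_t)
    inlet_flux_um3_s: np.ndarray  # (n_t,)
    velocity_profile: str  # plug | poiseuille
    dA_dt_um2_s: np.ndarray  # (n_z, n_t)

    def mean_velocity_mm_s(self) -> np.ndarray:
        """Cross-section mean axial-of-tube velocity Q/A on the grid, mm/s."""
        area = self.kinematics.area_um2
        open_ = area > np.pi * CLOSED_RADIUS_UM**2
        v = np.zeros_like(self.flux_um3_s)
        v[open_] = self.flux_um3_s[open_] / area[open_] * 1e-3  # um/s -> mm/s
        return v

    def flux_at(self, z_um: float, t_s: np.ndarray) -> np.ndarray:
        """Periodic-in-time linear interpolation of Q at one station."""
        kin = self.kinematics
        iz = int(np.argmin(np.abs(kin.z_um - z_um)))
        tt = np.asarray(t_s, dtype=float) % kin.period_s
        tp = np.concatenate([kin.t_s, [kin.period_s]])
        qp = np.concatenate([self.flux_um3_s[iz], [self.flux_um3_s[iz, 0]]])
        return np.interp(tt, tp, qp)

    def tube_velocity_mm_s(self, z_um: float, r_frac: np.ndarray, t_s: float) -> np.ndarray:
        """Along-tube velocity at fractional radius positions, one station/time."""
        kin = self.kinematics
        r = float(kin.radius_fn(np.asarray(z_um), np.asarray(t_s)))
        area = np.pi * r**2
        if r <= CLOSED_RADIUS_UM or area <= 0:
            return np.zeros_like(np.asarray(r_frac, dtype=float))
        q = float(self.flux_at(z_um, np.asarray([t_s]))[0])
        u_mean = q / area * 1e-3  # mm/s
        r_frac = np.clip(np.asarray(r_frac, dtype=float), 0.0, 1.0)
        if self.velocity_profile == "plug":
            return np.full_like(r_frac, u_mean)
        return 2.0 * u_mean * (1.0 - r_frac**2)


def derive_flow(
    kin: WallKinematics,
    inlet_flux_um3_s: np.ndarray | Callable[[np.ndarray], np.ndarray] | float,
    profile: str = "poiseuille",
) -> GroundTruthFlow:
    """Integrate mass conservation dA/dt + dQ/dz = 0 from the inlet.

    Q(z, t) = Q(z0, t) - int_{z0}^{z} dA/dt dz'. A closed cross-section
    (radius below the closure floor) carrying nonzero flux is physically
    impossible and raises :class:`OcclusionInconsistencyError`.
    """
    if profile not in ("plug", "poiseuille"):
        raise InvalidConfigurationError(f"unknown velocity profile {profile!r}")
    n_t = len(kin.t_s)
    if callable(inlet_flux_um3_s):
        q0 = np.asarray(inlet_flux_um3_s(kin.t_s), dtype=float)
    else:
        q0 = np.broadcast_to(np.asarray(inlet_flux_um3_s, dtype=float), (n_t,)).copy()
    if q0.shape != (n_t,):
        raise InvalidConfigurationError("inlet flux must match the kinematics time grid")

    cum, dA_dt = _wall_cumflux(kin)
    flux = q0[None, :] - cum

    closed = kin.radius_um <= CLOSED_RADIUS_UM
    if np.any(closed):
        tol = max(1e-9, 1e-3 * np.max(np.abs(flux)))
        if np.any(np.abs(flux[closed]) > tol):
            raise OcclusionInconsistencyError(
                "nonzero flux through a closed cross-section; "
                "use consistent_inlet_flux() to build an admissible inlet series"
            )
    return GroundTruthFlow(
        kinematics=kin,
        flux_um3_s=flux,
        inlet_flux_um3_s=q0,
        velocity_profile=profile,
        dA_dt_um2_s=dA_dt,
    )


def consistent_inlet_flux(
    kin: WallKinematics,
    drive_um3_s: np.ndarray | Callable[[np.ndarray], np.ndarray] | float = 0.0,
    drive_station_um: float | None = None,
) -> np.ndarray:
    """Inlet flux series admissible for a kinematics with closures.

    At times when some cross-section is closed, the inlet flux is fully
    determined by requiring zero flux through every closed station (the
    wall motion squeezes or draws all displaced volume); the free
    ``drive`` applies only while the whole tube is open. If
    ``drive_station_um`` is given, the drive prescribes the flux at that
    station instead of at the inlet (useful to impose a target flow at a
    measurement plane).
    """
    n_t = len(kin.t_s)
    if callable(drive_um3_s):
        drive = np.asarray(drive_um3_s(kin.t_s), dtype=float)
    else:
        drive = np.broadcast_to(np.asarray(drive_um3_s, dtype=float), (n_t,)).copy()

    cum, _ = _wall_cumflux(kin)  # (n_z, n_t)
    closed = kin.radius_um <= CLOSED_RADIUS_UM

    q0 = np.empty(n_t)
    scale = max(np.max(np.abs(cum)), 1e-9)
    if drive_station_um is None:
        iz_drive = 0
    else:
        iz_drive = int(np.argmin(np.abs(kin.z_um - drive_station_um)))
    for j in range(n_t):
        idx = np.nonzero(closed[:, j])[0]
        if len(idx):
            req = cum[idx, j]
            if np.ptp(req) > 1e-3 * scale:
                raise OcclusionInconsistencyError(
                    "disjoint closed regions demand incompatible inlet fluxes"
                )
            q0[j] = float(np.mean(req))
        else:
            q0[j] = drive[j] + cum[iz_drive, j]
    return q0


# ---------------------------------------------------------------------------
# acquisition plan and B-scan rendering
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionPlan:
    """Slow-axis acquisition schedule: where, how long, and at what phase."""

    slice_positions_um: np.ndarray
    frames_per_slice: int
    start_phase_per_slice: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.slice_positions_um = np.asarray(self.slice_positions_um, dtype=float)
        self.start_phase_per_slice = np.asarray(self.start_phase_per_slice, dtype=float)
        if len(self.slice_positions_um) != len(self.start_phase_per_slice):
            raise InvalidConfigurationError("one start phase per slice required")
        if np.any((self.start_phase_per_slice < 0) | (self.start_phase_per_slice >= 1)):
            raise InvalidConfigurationError("start phases must lie in [0, 1)")

    def validate_coverage(self, optics: OpticsConfig, period_s: float) -> None:
        if self.frames_per_slice / optics.b_scan_rate_hz < 2.0 * period_s:
            raise InvalidConfigurationError(
                "each slice must record at least two full heartbeat cycles"
            )


def random_plan(
    slice_positions_um: np.ndarray,
    frames_per_slice: int,
    seed: int,
) -> AcquisitionPlan:
    """Acquisition plan with independent uniform start phases per slice."""
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 1.0, size=len(slice_positions_um))
    return AcquisitionPlan(
        slice_positions_um=np.asarray(slice_positions_um, dtype=float),
        frames_per_slice=frames_per_slice,
        start_phase_per_slice=phases,
        seed=seed,
    )


#: speckle grain (axial, lateral) in micrometres — set by the imaging
#: resolution, not the pixel pitch
SPECKLE_GRAIN_UM = (2.0, 3.0)


def _speckle_field(rng: np.random.Generator, shape: tuple[int, int],
                   sigma: tuple[float, float] = (1.0, 1.5)) -> np.ndarray:
    """Spatially correlated circular complex Gaussian field, unit mean power."""
    f = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    f = gaussian_filter(f.real, sigma) + 1j * gaussian_filter(f.imag, sigma)
    power = np.mean(np.abs(f) ** 2)
    return (f / np.sqrt(power)).astype(np.complex128)


def _speckle_stack(
    rng: np.random.Generator,
    n_frames: int,
    shape: tuple[int, int],
    tau_frames: float | None,
    sigma: tuple[float, float] = (1.0, 1.5),
) -> np.ndarray:
    """Temporally evolving speckle: AR(1) in time, correlated in space.

    ``tau_frames`` is the 1/e decorrelation time; ``None`` freezes the
    pattern (fully developed static speckle). Frames one heartbeat apart
    are effectively independent for tau well below the period, emulating
    the scatterer rearrangement of living, deforming tissue — which is
    what lets cycle-compounded structural images average speckle down.
    """
    base = _speckle_field(rng, shape, sigma)
    if tau_frames is None or n_frames == 1:
        return np.broadcast_to(base, (n_frames,) + shape)
    rho = float(np.exp(-1.0 / tau_frames))
    innov_scale = np.sqrt(1.0 - rho**2)
    out = np.empty((n_frames,) + shape, dtype=np.complex128)
    out[0] = base
    for k in range(1, n_frames):
        out[k] = rho * out[k - 1] + innov_scale * _speckle_field(rng, shape, sigma)
    return out


def render_bscan_sequence(
    kin: WallKinematics | None,
    flow: GroundTruthFlow | None,
    optics: OpticsConfig,
    slice_position_um: float,
    n_frames: int,
    start_phase: float = 0.0,
    seed: int = 0,
    theta_deg: float = 60.0,
    image_shape: tuple[int, int] = (64, 64),
    wall_thickness_um: float = 16.0,
    wall_reflectivity: float = 1.0,
    blood_reflectivity: float = 0.32,
    background_reflectivity: float = 0.05,
    uniform_axial_velocity_mm_s: float | None = None,
    static_radius_um: float | None = None,
    speckle_tau_frames: float | None = 15.0,
    blood_tau_frames: float | None = 2.0,
) -> ComplexFrameSequence:
    """Render complex B-scan frames for one slice of the phantom.

    Each frame is a (depth, lateral) complex speckle image: bright wall
    annulus, dimmer blood-filled lumen, dark background. Within a frame,
    laterally adjacent columns are treated as consecutive A-scans; moving
    blood multiplies column ``j`` by ``exp(i * sum_{j'<=j} dphi(j'))`` with
    per-A-scan phase ``dphi = 4 pi n v_axial / (lambda fA)``, so a lag-one
    autocorrelation recovers ``dphi`` exactly (up to speckle and noise).

    ``uniform_axial_velocity_mm_s`` bypasses the flow field and imposes a
    constant axial velocity on the blood — the calibration mode used to
    verify the Doppler closed form. ``static_radius_um`` freezes the wall.
    ``speckle_tau_frames`` / ``blood_tau_frames`` set the temporal speckle
    decorrelation times of tissue and blood (``None`` freezes a pattern).
    """
    if kin is not None and not (
        kin.z_um[0] - 1e-9 <= slice_position_um <= kin.z_um[-1] + 1e-9
    ):
        raise InvalidConfigurationError("slice position outside the tube extent")
    rng = np.random.default_rng(seed)
    n_depth, n_lat = image_shape
    ax, lat = optics.axial_pixel_um, optics.lateral_pixel_um
    grain_px = (SPECKLE_GRAIN_UM[0] / ax, SPECKLE_GRAIN_UM[1] / lat)
    yy = (np.arange(n_depth) - (n_depth - 1) / 2.0) * ax
    xx = (np.arange(n_lat) - (n_lat - 1) / 2.0) * lat
    dist = np.hypot(yy[:, None], xx[None, :])  # um from lumen centre

    # blood speckle decorrelates much faster than the tissue wall: moving
    # erythrocytes rearrange within tens of milliseconds
    s_bg = _speckle_stack(rng, n_frames, image_shape, speckle_tau_frames, sigma=grain_px)
    s_wall = _speckle_stack(rng, n_frames, image_shape, speckle_tau_frames, sigma=grain_px)
    s_blood = _speckle_stack(rng, n_frames, image_shape, blood_tau_frames, sigma=grain_px)

    period = kin.period_s if kin is not None else 1.0
    t0 = start_phase * period
    times = t0 + np.arange(n_frames) / optics.b_scan_rate_hz

    cos_theta = np.cos(np.deg2rad(theta_deg))
    noise_var = wall_reflectivity**2 * 10.0 ** (-optics.snr_db / 10.0)
    noise_sigma = np.sqrt(noise_var / 2.0)

    frames = np.empty((n_frames, n_depth, n_lat), dtype=np.complex64)
    aliased = False
    for k, t in enumerate(times):
        if static_radius_um is not None:
            r = float(static_radius_um)
        else:
            r = float(kin.radius_fn(np.asarray(slice_position_um), np.asarray(t)))
        lumen = dist < r
        wall = (dist >= r) & (dist < r + wall_thickness_um)
        field = background_reflectivity * s_bg[k].copy()
        field[wall] = wall_reflectivity * s_wall[k][wall]
        field[lumen] = blood_reflectivity * s_blood[k][lumen]

        v_axial = np.zeros(image_shape)
        if r > CLOSED_RADIUS_UM:
            if uniform_axial_velocity_mm_s is not None:
                v_axial[lumen] = uniform_axial_velocity_mm_s
            elif flow is not None:
                r_frac = np.zeros(image_shape)
                r_frac[lumen] = dist[lumen] / r
                v_tube = flow.tube_velocity_mm_s(slice_position_um, r_frac[lumen], t)
                v_axial[lumen] = v_tube * cos_theta
        dphi = optics.phase_for_velocity(1.0) * v_axial  # rad per A-scan interval
        if np.any(np.abs(dphi) > np.pi):
            aliased = True
        phase = np.cumsum(dphi, axis=1)
        field = field * np.exp(1j * phase)
        field = field + noise_sigma * (
            rng.standard_normal(image_shape) + 1j * rng.standard_normal(image_shape)
        )
        frames[k] = field.astype(np.complex64)

    meta = {
        "theta_deg": theta_deg,
        "seed": seed,
        "start_phase": start_phase,
        "period_s": period,
        "wall_reflectivity": wall_reflectivity,
        "blood_reflectivity": blood_reflectivity,
        "warnings": ["doppler_aliasing"] if aliased else [],
    }
    return ComplexFrameSequence(
        frames=frames,
        optics=optics,
        slice_position_um=float(slice_position_um),
        timestamps_s=times,
        meta=meta,
    )


def acquire(
    kin: WallKinematics,
    flow: GroundTruthFlow,
    optics: OpticsConfig,
    plan: AcquisitionPlan,
    theta_deg: float = 60.0,
    **render_kwargs,
) -> list[ComplexFrameSequence]:
    """Render all slices of an acquisition plan with per-slice derived seeds."""
    plan.validate_coverage(optics, kin.period_s)
    seeds = np.random.SeedSequence(plan.seed).spawn(len(plan.slice_positions_um))
    out = []
    for pos, phase, ss in zip(plan.slice_positions_um, plan.start_phase_per_slice, seeds):
        seed = int(ss.generate_state(1)[0] % (2**31))
        out.append(
            render_bscan_sequence(
                kin, flow, optics, pos,
                n_frames=plan.frames_per_slice,
                start_phase=float(phase),
                seed=seed,
                theta_deg=theta_deg,
                **render_kwargs,
            )
        )
    return out
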