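"""Shared containers for complex OCT-like frame data and optics metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigurationError


@dataclass(frozen=True)
class OpticsConfig:
    """Optical and acquisition parameters of the (emulated) OCT system.

    Parameters
    ----------
    wavelength_m:
        Central wavelength of the light source, in meters.
    a_scan_rate_hz:
        A-scan (depth profile) rate ``fA``. Adjacent A-scans are separated
        by ``1/fA`` seconds; the Doppler phase shift accrues over this
        interval.
    b_scan_rate_hz:
        Frame (B-scan) rate, i.e. the temporal sampling rate of the
        cross-sectional movie at one slice position.
    refractive_index:
        Refractive index of the medium (blood), scaling the optical path.
    axial_pixel_um / lateral_pixel_um:
        Physical pixel pitch of the rendered/reconstructed images.
    snr_db:
        Signal-to-noise ratio of the rendered frames, relative to the
        brightest (wall) tissue signal.
    """

    wavelength_m: float = 810e-9
    a_scan_rate_hz: float = 68e3
    b_scan_rate_hz: float = 100.0
    refractive_index: float = 1.4
    axial_pixel_um: float = 2.0
    lateral_pixel_um: float = 2.0
    snr_db: float = 30.0

    def __post_init__(self) -> None:
        if self.wavelength_m <= 0 or self.a_scan_rate_hz <= 0:
            raise InvalidConfigurationError("wavelength and A-scan rate must be positive")
        if self.refractive_index <= 0:
            raise InvalidConfigurationError("refractive index must be positive")
        if self.b_scan_rate_hz <= 0:
            raise InvalidConfigurationError("B-scan rate must be positive")

    @property
    def nyquist_velocity_mm_s(self) -> float:
        """Largest unambiguous axial speed, ``lambda * fA / (4 n)``, in mm/s."""
        return self.wavelength_m * self.a_scan_rate_hz / (4.0 * self.refractive_index) * 1e3

    @property
    def velocity_per_radian_mm_s(self) -> float:
        """Axial velocity corresponding to one radian of inter-A-scan phase."""
        return (
            self.wavelength_m
            * self.a_scan_rate_hz
            / (4.0 * np.pi * self.refractive_index)
            * 1e3
        )

    def phase_for_velocity(self, v_axial_mm_s: float) -> float:
        """Inter-A-scan phase shift (rad) imposed by an axial velocity in mm/s."""
        return float(v_axial_mm_s) / self.velocity_per_radian_mm_s


@dataclass
class ComplexFrameSequence:
    """Time-ordered complex B-scans at one slow-axis position.

    ``frames`` has shape ``(time, depth, lateral)``. The inter-A-scan phase
    between laterally adjacent columns encodes axial velocity; the frame
    index encodes slow time at ``optics.b_scan_rate_hz``.
    """

    frames: np.ndarray
    optics: OpticsConfig
    slice_position_um: float
    timestamps_s: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidConfigurationError("frames must be (time, depth, lateral)")
        if len(self.timestamps_s) != self.frames.shape[0]:
            raise InvalidConfigurationError("one timestamp per frame required")
        dt = np.diff(self.timestamps_s)
        if len(dt) and (np.any(dt <= 0) or np.any(np.abs(dt - dt[0]) > 1e-9)):
            raise InvalidConfigurationError("timestamps must increase uniformly")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]
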