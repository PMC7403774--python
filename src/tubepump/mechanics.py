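"""Biomechanical observables of localized tube pumping.

From the lumen-area traces at the bracketing planes and the Doppler
velocity at the central plane, this module computes the three observables
of the pumping analysis:

* the wall-movement pressure-gradient proxy
  ``G(t) = (1/A3) dA3/dt - (1/A1) dA1/dt`` (units 1/s; viscosity is
  treated as a constant scale and dropped, so only relative dynamics and
  signs are meaningful; ``G > 0`` drives forward flow),
* the normalized viscous flow resistance ``Rnorm(t)``, the cycle-
  normalized ``1/Aa`` with range exactly [0, 1],
* the volumetric flow rate ``V(t)``, the Doppler-angle-corrected integral
  of axial velocity over the lumen cross-section (um^3/s).

Plus phase labelling (relaxation / contraction / closed) and the
suction-vs-pushing classification of each labelled interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import InvalidConfigurationError, UndefinedAngleError
from .lumen_measure import LumenTrace

__all__ = [
    "smooth_derivative",
    "wall_pressure_term",
    "pressure_gradient",
    "flow_resistance",
    "volumetric_flow_rate",
    "label_phases",
    "classify_mechanism",
    "HemodynamicSeries",
    "PhaseLabels",
]


@dataclass
class HemodynamicSeries:
    """Time-aligned pumping observables over one cycle.

    ``pressure_gradient`` may contain NaN where either lumen is closed
    (the proxy is undefined there and never extrapolated).
    """

    times_s: np.ndarray
    pressure_gradient: np.ndarray  # G(t), 1/s
    resistance_norm: np.ndarray  # [0, 1]
    flow_rate_um3_s: np.ndarray  # V(t)
    low_resistance_mask: np.ndarray
    smoothing_meta: dict


@dataclass
class PhaseLabels:
    """Tiling of the cycle into relaxation / contraction / closed intervals."""

    intervals: list[tuple[int, int, str]]  # [start, end) sample indices, circular
    labels: np.ndarray  # per-sample label strings
    basis: str = "L1+L3 area traces"


def smooth_derivative(
    series: np.ndarray,
    dt: float,
    window: int = 5,
    polyorder: int = 2,
) -> np.ndarray:
    """Savitzky-Golay first derivative with circular (cycle-periodic) padding."""
    y = np.asarray(series, dtype=float)
    if len(y) < 5:
        raise InvalidConfigurationError("need at least 5 samples")
    if window >= len(y):
        raise InvalidConfigurationError("smoothing window must be shorter than the series")
    if window % 2 == 0:
        raise InvalidConfigurationError("window must be odd")
    return savgol_filter(y, window, polyorder, deriv=1, delta=dt, mode="wrap")


def wall_pressure_term(
    trace: LumenTrace,
    window: int = 5,
    polyorder: int = 2,
    area_floor_um2: float | None = None,
) -> np.ndarray:
    """Local wall-movement pressure term ``p_w = -(1/A) dA/dt`` in 1/s.

    Expansion (dA/dt > 0) gives a negative term — local suction;
    contraction gives a positive term — local pushing. Closed phases are
    NaN (masked, not extrapolated).
    """
    a = trace.areas_mean_um2
    dt = float(np.mean(np.diff(trace.times_s)))
    dadt = smooth_derivative(a, dt, window=window, polyorder=polyorder)
    floor = area_floor_um2 if area_floor_um2 is not None else 4 * trace.pixel_area_um2
    out = np.full_like(a, np.nan)
    open_ = (~trace.closed_flag) & (a > floor)
    out[open_] = -dadt[open_] / a[open_]
    return out


def pressure_gradient(
    trace_l1: LumenTrace,
    trace_l3: LumenTrace,
    window: int = 5,
    polyorder: int = 2,
) -> np.ndarray:
    """Wall-movement pressure-gradient proxy between L1 and L3.

    ``G = p_w(L1) - p_w(L3)``; positive G means higher wall-generated
    pressure upstream, driving forward (L1 -> L3) flow. NaN wherever
    either plane is closed.
    """
    if not np.allclose(trace_l1.times_s, trace_l3.times_s):
        raise InvalidConfigurationError("traces must share the time grid")
    p1 = wall_pressure_term(trace_l1, window=window, polyorder=polyorder)
    p3 = wall_pressure_term(trace_l3, window=window, polyorder=polyorder)
    return p1 - p3


def flow_resistance(
    aa_um2: np.ndarray,
    closed_flag: np.ndarray | None = None,
    area_floor_um2: float = 16.0,
) -> np.ndarray:
    """Normalized viscous resistance: cycle-normalized 1/Aa in [0, 1].

    The raw resistance is ``1 / max(Aa, floor)`` (the floor bounds the
    closed-lumen resistance); normalization maps the cycle minimum to 0
    and the maximum to 1, and closed phases map to exactly 1.
    """
    aa = np.asarray(aa_um2, dtype=float)
    raw = 1.0 / np.maximum(aa, area_floor_um2)
    if closed_flag is not None:
        raw[np.asarray(closed_flag, dtype=bool)] = 1.0 / area_floor_um2
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-15 * max(hi, 1e-300):
        warnings.warn("constant averaged area: resistance normalization degenerate")
        return np.zeros_like(raw)
    rn = (raw - lo) / (hi - lo)
    if closed_flag is not None:
        rn[np.asarray(closed_flag, dtype=bool)] = 1.0
    return rn


def volumetric_flow_rate(
    velocity_plane_mm_s: np.ndarray,
    lumen_mask: np.ndarray,
    theta_rad: float,
    pixel_area_um2: float,
    angle_correction: str = "divide",
) -> float:
    """Volumetric flow rate through the lumen cross-section, in um^3/s.

    Integrates the signed axial Doppler velocity over the segmented lumen
    and corrects for the Doppler angle theta between flow and beam. With
    measurement planes perpendicular to the tube axis the beam sees
    ``va = v cos(theta)``, so the along-tube speed is recovered by
    *dividing* by cos(theta) (default); ``angle_correction="multiply"``
    applies the alternative reading of the integral.
    """
    if not (0 <= theta_rad < np.pi / 2):
        raise UndefinedAngleError("theta must lie in [0, pi/2)")
    mask = np.asarray(lumen_mask, dtype=bool)
    if mask.shape != np.asarray(velocity_plane_mm_s).shape:
        raise InvalidConfigurationError("mask must match the velocity image")
    if not mask.any():
        return 0.0
    v = np.asarray(velocity_plane_mm_s, dtype=float)[mask] * 1e3  # mm/s -> um/s
    if angle_correction == "divide":
        v = v / np.cos(theta_rad)
    elif angle_correction == "multiply":
        v = v * np.cos(theta_rad)
    else:
        raise InvalidConfigurationError("angle_correction must be 'divide' or 'multiply'")
    return float(np.sum(v) * pixel_area_um2)


def label_phases(
    trace_l1: LumenTrace,
    trace_l3: LumenTrace,
    tau_frac: float = 0.02,
    window: int = 5,
) -> PhaseLabels:
    """Tile the cycle into relaxation, contraction, and closed intervals.

    Relaxation: both lumens expanding faster than a small threshold tau;
    contraction: both shrinking; closed: both flagged closed. Unlabelled
    samples join the nearest labelled interval (circularly), so the
    intervals always tile the cycle.
    """
    dt = float(np.mean(np.diff(trace_l1.times_s)))
    d1 = smooth_derivative(trace_l1.areas_mean_um2, dt, window=window)
    d3 = smooth_derivative(trace_l3.areas_mean_um2, dt, window=window)
    tau = tau_frac * max(np.max(np.abs(d1)), np.max(np.abs(d3)), 1e-300)
    n = len(d1)
    lab = np.array([""] * n, dtype=object)
    both_closed = trace_l1.closed_flag & trace_l3.closed_flag
    lab[both_closed] = "closed"
    grow = (d1 > tau) & (d3 > tau) & ~both_closed
    shrink = (d1 < -tau) & (d3 < -tau) & ~both_closed
    lab[grow] = "relaxation"
    lab[shrink] = "contraction"

    unl = np.nonzero(lab == "")[0]
    if len(unl) == n:
        lab[:] = "closed" if both_closed.all() else "relaxation"
    else:
        labelled = np.nonzero(lab != "")[0]
        for i in unl:
            d = np.minimum((labelled - i) % n, (i - labelled) % n)
            lab[i] = lab[labelled[np.argmin(d)]]

    # rotate so a label boundary sits first, then collect circular runs
    boundaries = [i for i in range(n) if lab[i] != lab[i - 1]]
    start = boundaries[0] if boundaries else 0
    order = [(start + k) % n for k in range(n)]
    intervals: list[tuple[int, int, str]] = []
    seg_start, cur_lab = order[0], lab[order[0]]
    for pos in order[1:]:
        if lab[pos] != cur_lab:
            intervals.append((seg_start, pos, str(cur_lab)))
            seg_start, cur_lab = pos, lab[pos]
    intervals.append((seg_start, order[0], str(cur_lab)))
    return PhaseLabels(intervals=intervals, labels=lab.astype(str))


def classify_mechanism(
    g: np.ndarray,
    v: np.ndarray,
    labels: PhaseLabels,
    low_resistance_mask: np.ndarray,
    evidence_threshold: float = 0.6,
) -> dict:
    """Per-interval suction/pushing evidence and a combined mechanism tag.

    Over each relaxation interval, sign agreement of G and V among
    low-resistance unmasked samples is evidence of suction (active
    expansion generating the pressure gradients that pull the flow);
    over each contraction interval, jointly positive G and V is evidence
    of pushing. The combined tag is ``suction``, ``pushing``, ``mixed``
    (both present) or ``indeterminate``.
    """
    g = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    n = len(g)
    usable = low_resistance_mask & np.isfinite(g) & np.isfinite(v)
    report = {"intervals": [], "tag": "indeterminate"}
    saw_suction = saw_pushing = False
    any_usable = False
    for start, end, lab in labels.intervals:
        idx = np.arange(start, end if end > start else end + n) % n
        sel = idx[usable[idx]]
        entry = {"label": lab, "start": int(start), "end": int(end),
                 "n_usable": int(len(sel)), "evidence": None, "mechanism": None}
        if lab in ("relaxation", "contraction") and len(sel) > 0:
            any_usable = True
            if lab == "relaxation":
                agree = np.sign(g[sel]) == np.sign(v[sel])
            else:
                agree = (g[sel] > 0) & (v[sel] > 0)
            frac = float(np.mean(agree))
            entry["evidence"] = frac
            if frac >= evidence_threshold:
                mech = "suction" if lab == "relaxation" else "pushing"
                entry["mechanism"] = mech
                saw_suction |= mech == "suction"
                saw_pushing |= mech == "pushing"
        report["intervals"].append(entry)
    if saw_suction and saw_pushing:
        report["tag"] = "mixed"
    elif saw_suction:
        report["tag"] = "suction"
    elif saw_pushing:
        report["tag"] = "pushing"
    elif any_usable:
        report["tag"] = "indeterminate"
    return report
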