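"""4D reconstruction from complex frame sequences.

Structural imaging (log intensity), axial velocimetry via the windowed
Kasai autocorrelation of laterally adjacent A-scans, heartbeat period
estimation, and retrospective gating: folding each slice's frame sequence
into one canonical cardiac cycle and phase-aligning neighbouring slices by
structural cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import (
    AperiodicityError,
    InvalidConfigurationError,
    SynchronizationError,
)
from .frames import ComplexFrameSequence, OpticsConfig

__all__ = [
    "Volume4D",
    "structural_image",
    "kasai_axial_velocity",
    "estimate_period",
    "fold_cycle",
    "gate_and_synchronize",
]


@dataclass
class Volume4D:
    """Phase-synchronized 4D structural + axial-velocity dataset.

    Arrays are ``(phase, slice, depth, lateral)``; ``volume_rate_hz`` is
    the reconstruction volume rate (equal to the B-scan rate), so phase
    ``p`` corresponds to cycle time ``p / volume_rate_hz``.
    """

    structural: np.ndarray
    velocity_mm_s: np.ndarray
    volume_rate_hz: float
    period_s: float
    phase_count: int
    slice_positions_um: np.ndarray
    optics: OpticsConfig
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.structural.shape != self.velocity_mm_s.shape:
            raise InvalidConfigurationError("structural/velocity shape mismatch")
        if self.structural.shape[0] != self.phase_count:
            raise InvalidConfigurationError("first axis must be cycle phase")

    @property
    def phase_times_s(self) -> np.ndarray:
        return np.arange(self.phase_count) / self.volume_rate_hz

    @property
    def pixel_sizes_um(self) -> tuple[float, float, float]:
        """(slice step, axial pixel, lateral pixel) in micrometres."""
        pos = self.slice_positions_um
        step = float(np.mean(np.diff(pos))) if len(pos) > 1 else 1.0
        return (step, self.optics.axial_pixel_um, self.optics.lateral_pixel_um)


def structural_image(seq: ComplexFrameSequence | np.ndarray) -> np.ndarray:
    """Log-scale intensity 20*log10(|I| + eps) of each pixel, in dB.

    The floor ``eps`` is 1e-12 of the peak amplitude, so an all-zero
    frame maps to the floor value instead of -inf.
    """
    frames = seq.frames if isinstance(seq, ComplexFrameSequence) else np.asarray(seq)
    if frames.size == 0:
        raise InvalidConfigurationError("empty frame stack")
    amp = np.abs(frames)
    peak = amp.max()
    eps = 1e-12 * peak if peak > 0 else 1e-12
    return 20.0 * np.log10(amp + eps)


def kasai_axial_velocity(
    seq: ComplexFrameSequence,
    window: tuple[int, int] = (3, 3),
    low_confidence_rel: float = 1e-6,
    return_flags: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Axial velocity (mm/s) per pixel via the windowed Kasai estimator.

    For each frame, lag-one conjugate products of laterally adjacent
    A-scans are summed over an ``M x N`` window (``M`` depth pixels by
    ``N`` lateral A-scans, i.e. ``N - 1`` products) and the four-quadrant
    argument of the sum is scaled by ``lambda fA / (4 pi n)``. Positive
    velocity means motion towards the beam.

    Windows where both the real and imaginary accumulations are at the
    noise floor are set to zero velocity and flagged low-confidence.
    """
    m, n = window
    if m < 1 or n < 2:
        raise InvalidConfigurationError("window must be at least 1 x 2 (M >= 1, N >= 2)")
    frames = seq.frames
    if m > frames.shape[1] or n > frames.shape[2]:
        raise InvalidConfigurationError("window does not fit inside the frame")
    prod = frames[:, :, 1:] * np.conj(frames[:, :, :-1])  # (T, depth, lat-1)
    size = (1, m, n - 1)
    re = uniform_filter(prod.real.astype(np.float64), size=size, mode="nearest")
    im = uniform_filter(prod.imag.astype(np.float64), size=size, mode="nearest")
    mag = np.hypot(re, im)
    floor = low_confidence_rel * max(float(np.mean(np.abs(prod))), 1e-300)
    low_conf = mag < floor
    phi = np.arctan2(im, re)
    phi[low_conf] = 0.0
    v = seq.optics.velocity_per_radian_mm_s * phi
    # pad the missing last lateral column so output matches the frame grid
    v = np.concatenate([v, v[:, :, -1:]], axis=2)
    if return_flags:
        flags = np.concatenate([low_conf, low_conf[:, :, -1:]], axis=2)
        return v, flags
    return v


def _similarity_trace(struct: np.ndarray, downsample: int = 4) -> np.ndarray:
    """Per-frame feature vectors: coarsely downsampled log-intensity frames."""
    t, d, l = struct.shape
    dd, ll = d // downsample * downsample, l // downsample * downsample
    x = struct[:, :dd, :ll].reshape(t, dd // downsample, downsample,
                                    ll // downsample, downsample).mean(axis=(2, 4))
    return x.reshape(t, -1)


def _autocorr_of_frames(feat: np.ndarray) -> np.ndarray:
    """Mean Pearson correlation between frames lag apart, for each lag."""
    x = feat - feat.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(x, axis=1)
    if np.all(norm < 1e-12):
        raise AperiodicityError("constant frame sequence has no heartbeat")
    norm = np.where(norm < 1e-12, 1.0, norm)
    x = x / norm[:, None]
    t = len(x)
    ac = np.empty(t)
    gram = x @ x.T
    for lag in range(t):
        ac[lag] = np.mean(np.diagonal(gram, offset=lag))
    return ac


def estimate_period(
    seq: ComplexFrameSequence,
    min_period_frames: int = 5,
    peak_threshold: float = 0.2,
) -> tuple[int, float]:
    """Heartbeat period of a frame sequence, in frames and in seconds.

    The period is the first dominant peak of the frame-similarity
    autocorrelation (mean Pearson correlation of coarsened log-intensity
    frames at each lag), refined to sub-frame precision by parabolic
    interpolation around the peak.
    """
    struct = structural_image(seq)
    feat = _similarity_trace(struct)
    ac = _autocorr_of_frames(feat)
    n = len(ac)
    if n < 2 * min_period_frames:
        raise AperiodicityError("sequence too short to contain two cycles")
    # first *dominant* local maximum beyond the zero-lag lobe: shallow
    # ripples in the decorrelation valley must not pass for a heartbeat
    search = ac[min_period_frames : n - 1]
    dominance = max(peak_threshold, 0.5 * float(search.max()))
    candidates = np.nonzero(
        (search >= ac[min_period_frames - 1 : n - 2])
        & (search >= ac[min_period_frames + 1 : n])
        & (search > dominance)
    )[0]
    if len(candidates) == 0:
        raise AperiodicityError("no autocorrelation peak above threshold")
    # dominant first peak: among candidates near the first, take the best
    first = candidates[0] + min_period_frames
    window = [c + min_period_frames for c in candidates
              if c + min_period_frames <= first * 1.2]
    peak = max(window, key=lambda i: ac[i])
    # parabolic sub-frame refinement
    if 0 < peak < n - 1:
        y0, y1, y2 = ac[peak - 1], ac[peak], ac[peak + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    frac = peak + delta
    dt = float(np.mean(np.diff(seq.timestamps_s)))
    return int(round(frac)), frac * dt


def fold_cycle(
    seq: ComplexFrameSequence,
    period_frames: float,
    phase_count: int,
    window: tuple[int, int] = (3, 3),
) -> tuple[np.ndarray, np.ndarray]:
    """Fold one slice into a canonical cycle of ``phase_count`` bins.

    Frames are assigned to their nearest phase bin and averaged across
    cycles — intensity is compounded linearly (speckle-reducing) and
    converted to dB afterwards; Kasai velocities are averaged directly.
    """
    amp2 = np.abs(seq.frames).astype(float) ** 2
    vel = kasai_axial_velocity(seq, window=window)
    n = seq.n_frames
    phases = (np.arange(n) / period_frames) % 1.0
    bins = np.floor(phases * phase_count + 0.5).astype(int) % phase_count
    i_out = np.zeros((phase_count,) + amp2.shape[1:])
    v_out = np.zeros_like(i_out)
    counts = np.zeros(phase_count)
    for k in range(n):
        b = bins[k]
        i_out[b] += amp2[k]
        v_out[b] += vel[k]
        counts[b] += 1
    empty = counts == 0
    counts = np.where(empty, 1, counts)
    i_out /= counts[:, None, None]
    v_out /= counts[:, None, None]
    # fill any empty bin from its nearest populated neighbour
    if np.any(empty):
        pop = np.nonzero(~empty)[0]
        for b in np.nonzero(empty)[0]:
            near = pop[np.argmin(np.minimum(np.abs(pop - b), phase_count - np.abs(pop - b)))]
            i_out[b] = i_out[near]
            v_out[b] = v_out[near]
    peak = i_out.max()
    eps = 1e-24 * peak if peak > 0 else 1e-24
    s_out = 10.0 * np.log10(i_out + eps)
    return s_out, v_out


def _best_circular_shift(ref_feat: np.ndarray, mov_feat: np.ndarray) -> float:
    """Circular phase shift of ``mov`` maximizing mean correlation with ``ref``.

    Returns a fractional shift: integer argmax refined by parabolic
    interpolation of the correlation score. Integer ties are broken in
    favour of the smallest absolute (signed) shift.
    """
    p = len(ref_feat)
    a = ref_feat - ref_feat.mean(axis=1, keepdims=True)
    b = mov_feat - mov_feat.mean(axis=1, keepdims=True)
    a = a / np.maximum(np.linalg.norm(a, axis=1, keepdims=True), 1e-12)
    b = b / np.maximum(np.linalg.norm(b, axis=1, keepdims=True), 1e-12)
    scores = np.empty(p)
    for s in range(p):
        scores[s] = np.mean(np.sum(a * np.roll(b, -s, axis=0), axis=1))
    best = np.max(scores)
    ties = np.nonzero(scores >= best - 1e-12)[0]
    signed = np.where(ties > p // 2, ties - p, ties)
    peak = int(ties[np.argmin(np.abs(signed))])
    y0, y1, y2 = scores[(peak - 1) % p], scores[peak], scores[(peak + 1) % p]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
    return peak + float(np.clip(delta, -0.5, 0.5))


def gate_and_synchronize(
    slices: list[ComplexFrameSequence],
    window: tuple[int, int] = (3, 3),
    phase_count: int | None = None,
    max_period_spread: float = 0.05,
) -> Volume4D:
    """Retrospectively gate a list of slice sequences into a Volume4D.

    Each slice is folded into one cycle; adjacent slices are then
    phase-aligned by maximizing the normalized cross-correlation of their
    structural stacks over circular phase shifts, and the alignment is
    propagated from the first (reference) slice.
    """
    if len(slices) == 0:
        raise InvalidConfigurationError("no slices given")
    optics = slices[0].optics
    for s in slices[1:]:
        if s.optics != optics:
            raise SynchronizationError("slices must share optics configuration")

    periods_frames, periods_s = [], []
    for s in slices:
        pf, ps = estimate_period(s)
        periods_frames.append(pf)
        periods_s.append(ps)
    periods_s = np.asarray(periods_s)
    med = float(np.median(periods_s))
    bad = np.nonzero(np.abs(periods_s - med) > max_period_spread * med)[0]
    if len(bad):
        raise SynchronizationError(
            f"inconsistent heartbeat periods (>{max_period_spread:.0%} spread) "
            f"in slices {bad.tolist()}"
        )
    period_frames = med * optics.b_scan_rate_hz
    if phase_count is None:
        phase_count = int(round(period_frames))

    folded = [fold_cycle(s, period_frames, phase_count, window=window) for s in slices]
    feats = [_similarity_trace(sf) for sf, _ in folded]

    # accumulate fractional pairwise shifts and round the *cumulative*
    # value, so per-pair rounding errors do not random-walk along the chain
    cum = 0.0
    shifts = [0]
    for i in range(1, len(slices)):
        rel = _best_circular_shift(feats[i - 1], feats[i])
        rel = (rel + phase_count / 2) % phase_count - phase_count / 2  # signed
        cum += rel
        shifts.append(int(round(cum)) % phase_count)

    structural = np.empty((phase_count, len(slices)) + folded[0][0].shape[1:])
    velocity = np.empty_like(structural)
    for i, ((sf, vf), sh) in enumerate(zip(folded, shifts)):
        structural[:, i] = np.roll(sf, -sh, axis=0)
        velocity[:, i] = np.roll(vf, -sh, axis=0)

    vmax = optics.nyquist_velocity_mm_s
    velocity = np.clip(velocity, -vmax, vmax)
    return Volume4D(
        structural=structural,
        velocity_mm_s=velocity,
        volume_rate_hz=optics.b_scan_rate_hz,
        period_s=med,
        phase_count=phase_count,
        slice_positions_um=np.asarray([s.slice_position_um for s in slices]),
        optics=optics,
        meta={
            "applied_shifts": shifts,
            "periods_s": periods_s.tolist(),
            "theta_deg": slices[0].meta.get("theta_deg"),
        },
    )
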