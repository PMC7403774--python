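"""Measurement planes and endocardial lumen area traces.

Three planes perpendicular to the tube axis (L1, L2, L3 in the direction
of forward flow, default 30 um apart) intersect the reconstructed 4D
dataset. At each plane and phase the blood-filled lumen is segmented from
the structural image — the blood speckle is darker than the wall — and
the cross-sectional area A(t) is measured with several threshold-
perturbed replicates emulating the variability of repeated manual
segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import (
    binary_erosion,
    binary_fill_holes,
    binary_opening,
    gaussian_filter,
    map_coordinates,
)
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label

from .errors import (
    AmbiguousSegmentationError,
    InvalidConfigurationError,
    OutOfBoundsError,
)
from .oct_recon import Volume4D

#: lumen areas below this many pixels count as closed (sub-resolution)
CLOSURE_PIXELS = 4

#: physical closure floor: one optical resolution cell (~4 um beam), um^2.
#: A lumen smaller than this is not measurable regardless of pixel pitch.
CLOSURE_AREA_UM2 = 16.0


@dataclass(frozen=True)
class MeasurementPlane:
    """One measurement plane perpendicular to the tube axis.

    ``origin_um`` and ``normal`` live in volume physical coordinates
    (slice-axis, depth, lateral), in micrometres from the volume corner.
    """

    label: str
    origin_um: np.ndarray
    normal: np.ndarray
    pixel_um: float = 2.0
    half_extent_um: float = 60.0


def place_planes(
    axis_origin_um: np.ndarray,
    axis_direction: np.ndarray,
    spacing_um: float = 30.0,
    pixel_um: float = 2.0,
    half_extent_um: float = 60.0,
) -> tuple[MeasurementPlane, MeasurementPlane, MeasurementPlane]:
    """Place L1, L2, L3 along the tube axis; L2 sits at ``axis_origin_um``.

    L1 and L3 are one ``spacing_um`` upstream and downstream of L2, so
    the measured region spans twice the spacing along the axis. All three
    planes share the same normal (the forward-flow direction).
    """
    d = np.asarray(axis_direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise InvalidConfigurationError("axis direction must be nonzero")
    if spacing_um <= 0:
        raise InvalidConfigurationError("plane spacing must be positive")
    d = d / nrm
    o = np.asarray(axis_origin_um, dtype=float)
    mk = lambda lab, off: MeasurementPlane(
        label=lab, origin_um=o + off * d, normal=d,
        pixel_um=pixel_um, half_extent_um=half_extent_um,
    )
    return mk("L1", -spacing_um), mk("L2", 0.0), mk("L3", +spacing_um)


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    helper = np.array([0.0, 1.0, 0.0]) if abs(n[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def extract_plane_image(
    vol: Volume4D,
    plane: MeasurementPlane,
    phase: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinearly resample the structural and velocity channels onto a plane.

    Returns two 2D images on the plane's pixel grid; velocity is resampled
    as signed axial values. For a plane aligned with the slice axis this
    reduces to (an interpolation of) a direct array slice.
    """
    if not (0 <= phase < vol.phase_count):
        raise OutOfBoundsError(f"phase {phase} outside [0, {vol.phase_count})")
    sizes = np.asarray(vol.pixel_sizes_um)
    shape = np.asarray(vol.structural.shape[1:], dtype=float)
    origin_vox = plane.origin_um / sizes
    if np.any(origin_vox < -0.5) or np.any(origin_vox > shape - 0.5):
        raise OutOfBoundsError("plane origin outside the volume")

    e1, e2 = _plane_basis(plane.normal)
    n_px = int(round(2 * plane.half_extent_um / plane.pixel_um)) + 1
    uu = (np.arange(n_px) - (n_px - 1) / 2.0) * plane.pixel_um
    pts = (
        plane.origin_um[None, None, :]
        + uu[:, None, None] * e1[None, None, :]
        + uu[None, :, None] * e2[None, None, :]
    )  # (n, n, 3) in um
    coords = (pts / sizes[None, None, :]).transpose(2, 0, 1)  # (3, n, n) voxel units
    struct = map_coordinates(vol.structural[phase], coords, order=1, mode="nearest")
    velo = map_coordinates(vol.velocity_mm_s[phase], coords, order=1, mode="nearest")
    if not np.isfinite(struct).all():
        raise OutOfBoundsError("plane does not intersect the volume")
    return struct, velo


@dataclass
class SegmentationConfig:
    """Settings for threshold-based lumen segmentation."""

    method: str = "threshold"  # threshold | imported_mask
    threshold_db: float | None = None  # None -> Otsu inside the ROI
    replicate_delta_frac: float = 0.05  # threshold perturbation, fraction of range
    n_replicates: int = 3
    roi_radius_frac: float = 0.85  # ROI disk radius as a fraction of half-extent
    ambiguity_ratio: float = 0.8  # second/first component size triggering ambiguity
    smooth_sigma_px: float = 1.0  # pre-threshold smoothing (speckle suppression)
    opening_iterations: int = 1  # severs speckle leaks through the wall ring


def segment_lumen(
    plane_image: np.ndarray,
    config: SegmentationConfig | None = None,
    imported_masks: list[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Segment the (dark) blood-filled lumen; returns replicate masks.

    The lumen is the connected below-threshold component containing the
    image centre, hole-filled. Replicates perturb the threshold by
    ``+-delta`` (a fraction of the intensity range) to emulate the spread
    of repeated manual segmentation. A closed lumen (bright wall tissue at
    the centre) yields empty masks, not an error. If several dark
    components of similar size touch the ROI and none contains the
    centre, the segmentation is ambiguous and a ROI must be supplied.
    """
    cfg = config or SegmentationConfig()
    img = np.asarray(plane_image, dtype=float)
    if not np.isfinite(img).all():
        raise InvalidConfigurationError("plane image must be finite")
    if cfg.method == "imported_mask":
        if not imported_masks:
            raise InvalidConfigurationError("imported_mask method needs masks")
        for m in imported_masks:
            if m.shape != img.shape:
                raise InvalidConfigurationError("imported mask shape mismatch")
        return [m.astype(bool) for m in imported_masks]

    if cfg.smooth_sigma_px > 0:
        img = gaussian_filter(img, cfg.smooth_sigma_px)
    n0, n1 = img.shape
    yy, xx = np.mgrid[0:n0, 0:n1]
    cy, cx = (n0 - 1) / 2.0, (n1 - 1) / 2.0
    roi = np.hypot(yy - cy, xx - cx) <= cfg.roi_radius_frac * min(cy, cx)

    # three intensity classes inside the ROI (background, blood, wall);
    # the lumen boundary is the upper threshold, and the gap between the
    # two thresholds is the intensity range relevant to that boundary
    # (the replicate perturbation scale). Fall back to plain Otsu on
    # degenerate histograms (e.g. fully closed lumen).
    vals = img[roi]
    try:
        lo_thr, hi_thr = (float(t) for t in threshold_multiotsu(vals, classes=3))
        span = hi_thr - lo_thr
    except ValueError:
        hi_thr = float(threshold_otsu(vals))
        span = 10.0
    base_thr = hi_thr if cfg.threshold_db is None else float(cfg.threshold_db)
    deltas = np.linspace(-1.0, 1.0, max(cfg.n_replicates, 1))
    if cfg.n_replicates == 1:
        deltas = np.array([0.0])

    edge = roi & ~binary_erosion(roi, iterations=2)

    masks = []
    for d in deltas:
        thr = base_thr + d * cfg.replicate_delta_frac * span
        dark_raw = (img < thr) & roi
        if not dark_raw.any():
            masks.append(np.zeros_like(dark_raw))
            continue
        # wide speckle fades can breach the wall ring and connect the lumen
        # to the background; progressively stronger opening severs the leak
        found = None
        for extra in (0, 2, 4):
            its = cfg.opening_iterations + extra
            dark = binary_opening(dark_raw, iterations=its) if its > 0 else dark_raw
            lab = cc_label(dark)
            centre_lab = lab[int(round(cy)), int(round(cx))]
            if centre_lab != 0 and not np.any((lab == centre_lab) & edge):
                found = binary_fill_holes(lab == centre_lab)
                break
        if found is not None:
            masks.append(found)
            continue
        its = cfg.opening_iterations
        dark = binary_opening(dark_raw, iterations=its) if its > 0 else dark_raw
        lab = cc_label(dark)
        # centre not inside a dark interior component: candidates are dark
        # components enclosed by the (bright) wall, i.e. not touching the
        # ROI boundary — boundary-touching dark pixels are background
        interior = [
            l for l in range(1, lab.max() + 1)
            if not np.any((lab == l) & edge)
        ]
        sizes = np.array([(lab == l).sum() for l in interior])
        big = [l for l, s in zip(interior, sizes) if s > CLOSURE_PIXELS]
        if len(big) == 0:
            masks.append(np.zeros_like(dark))  # closed lumen
            continue
        order = np.argsort([-(lab == l).sum() for l in big])
        if len(big) > 1:
            s0 = (lab == big[order[0]]).sum()
            s1 = (lab == big[order[1]]).sum()
            # speckle-scale blobs never make the segmentation ambiguous
            if s1 >= cfg.ambiguity_ratio * s0 and s1 > 6 * CLOSURE_PIXELS:
                raise AmbiguousSegmentationError(
                    "multiple lumen candidates of similar size; supply a ROI"
                )
        masks.append(binary_fill_holes(lab == big[order[0]]))
    return masks


@dataclass
class LumenTrace:
    """Per-plane lumen area over one cycle, with replicate statistics."""

    plane_label: str
    times_s: np.ndarray
    areas_mean_um2: np.ndarray
    areas_std_um2: np.ndarray
    replicates_um2: np.ndarray  # (phase, replicate)
    closed_flag: np.ndarray  # bool per phase
    pixel_area_um2: float

    def effective_radius_um(self) -> np.ndarray:
        return np.sqrt(np.maximum(self.areas_mean_um2, 0.0) / np.pi)


def pooled_threshold(images: list[np.ndarray], config: SegmentationConfig) -> float:
    """One lumen threshold for a whole cycle of plane images.

    Pools ROI pixels over all phases before the three-class split, so the
    criterion does not drift at phases where the blood class is small —
    the analogue of a human segmenting all time points consistently.
    """
    img0 = np.asarray(images[0], dtype=float)
    n0, n1 = img0.shape
    yy, xx = np.mgrid[0:n0, 0:n1]
    cy, cx = (n0 - 1) / 2.0, (n1 - 1) / 2.0
    roi = np.hypot(yy - cy, xx - cx) <= config.roi_radius_frac * min(cy, cx)
    if config.smooth_sigma_px > 0:
        pool = np.concatenate(
            [gaussian_filter(np.asarray(im, dtype=float), config.smooth_sigma_px)[roi]
             for im in images]
        )
    else:
        pool = np.concatenate([np.asarray(im, dtype=float)[roi] for im in images])
    try:
        return float(threshold_multiotsu(pool, classes=3)[-1])
    except ValueError:
        return float(threshold_otsu(pool))


def area_trace(
    vol: Volume4D,
    plane: MeasurementPlane,
    config: SegmentationConfig | None = None,
    imported_masks: list[list[np.ndarray]] | None = None,
) -> LumenTrace:
    """Segment every phase at one plane and collect the area time series.

    Unless a fixed threshold is configured, a single pooled threshold is
    estimated from all phases and used throughout the cycle.
    """
    cfg = config or SegmentationConfig()
    pixel_area = plane.pixel_um**2
    closure_area = max(CLOSURE_PIXELS * pixel_area, CLOSURE_AREA_UM2)
    images = [extract_plane_image(vol, plane, p)[0] for p in range(vol.phase_count)]
    if cfg.threshold_db is None and cfg.method == "threshold":
        from dataclasses import replace

        cfg = replace(cfg, threshold_db=pooled_threshold(images, cfg))
    reps_all = []
    for p, struct in enumerate(images):
        masks = segment_lumen(
            struct, cfg,
            imported_masks=None if imported_masks is None else imported_masks[p],
        )
        reps_all.append([m.sum() * pixel_area for m in masks])
    reps = np.asarray(reps_all, dtype=float)
    mean = reps.mean(axis=1)
    std = reps.std(axis=1)
    closed = mean < closure_area
    return LumenTrace(
        plane_label=plane.label,
        times_s=vol.phase_times_s,
        areas_mean_um2=mean,
        areas_std_um2=std,
        replicates_um2=reps,
        closed_flag=closed,
        pixel_area_um2=pixel_area,
    )


def averaged_area(trace_l1: LumenTrace, trace_l3: LumenTrace) -> np.ndarray:
    """Region-averaged lumen area Aa(t) = (A_L1 + A_L3) / 2, using means."""
    if len(trace_l1.times_s) != len(trace_l3.times_s) or not np.allclose(
        trace_l1.times_s, trace_l3.times_s
    ):
        raise InvalidConfigurationError("traces must share the time grid")
    return 0.5 * (trace_l1.areas_mean_um2 + trace_l3.areas_mean_um2)


def fit_centerline(vol: Volume4D, phase: int = 0, threshold_db: float | None = None):
    """Convenience: straight-line fit to open-lumen centroids across slices.

    Returns ``(origin_um, direction)`` in volume physical coordinates;
    useful when no tube axis is supplied in the configuration.
    """
    sizes = vol.pixel_sizes_um
    pts = []
    for i in range(vol.structural.shape[1]):
        img = vol.structural[phase, i]
        thr = threshold_db if threshold_db is not None else float(threshold_otsu(img))
        dark = img < thr
        lab = cc_label(dark)
        c = lab[img.shape[0] // 2, img.shape[1] // 2]
        if c == 0:
            continue
        ys, xs = np.nonzero(lab == c)
        pts.append([i * sizes[0], ys.mean() * sizes[1], xs.mean() * sizes[2]])
    pts = np.asarray(pts)
    if len(pts) < 2:
        raise InvalidConfigurationError("too few open slices to fit a centerline")
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    direction = vt[0]
    if direction[0] < 0:
        direction = -direction
    return centroid, direction
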