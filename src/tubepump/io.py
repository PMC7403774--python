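"""HDF5 / TIFF / CSV persistence for phantom frames and 4D volumes."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .frames import ComplexFrameSequence, OpticsConfig
from .oct_recon import Volume4D

_OPTICS_FIELDS = (
    "wavelength_m",
    "a_scan_rate_hz",
    "b_scan_rate_hz",
    "refractive_index",
    "axial_pixel_um",
    "lateral_pixel_um",
    "snr_db",
)


def _write_optics(grp: h5py.Group, optics: OpticsConfig) -> None:
    for f in _OPTICS_FIELDS:
        grp.attrs[f] = getattr(optics, f)


def _read_optics(grp: h5py.Group) -> OpticsConfig:
    return OpticsConfig(**{f: float(grp.attrs[f]) for f in _OPTICS_FIELDS})


def save_frames_h5(
    path: str | Path,
    sequences: list[ComplexFrameSequence],
    truth: dict[str, np.ndarray] | None = None,
) -> None:
    """Write rendered slice sequences (and optional ground truth) to HDF5.

    Layout: ``/frames`` complex64 of shape (slice, time, depth, lateral),
    ``/meta`` (optics attrs, slice positions, start phases, timestamps),
    ``/truth`` ground-truth arrays when supplied.
    """
    path = Path(path)
    stack = np.stack([s.frames for s in sequences]).astype(np.complex64)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=stack, compression="gzip", compression_opts=1)
        meta = h5.create_group("meta")
        _write_optics(meta, sequences[0].optics)
        meta.create_dataset(
            "slice_positions_um", data=[s.slice_position_um for s in sequences]
        )
        meta.create_dataset(
            "start_times_s", data=[s.timestamps_s[0] for s in sequences]
        )
        meta.attrs["theta_deg"] = sequences[0].meta.get("theta_deg", 0.0)
        meta.attrs["period_s"] = sequences[0].meta.get("period_s", 0.0)
        meta.attrs["per_slice_meta"] = json.dumps(
            [{k: v for k, v in s.meta.items() if not isinstance(v, np.ndarray)}
             for s in sequences]
        )
        if truth:
            tg = h5.create_group("truth")
            for k, v in truth.items():
                tg.create_dataset(k, data=np.asarray(v))


def load_frames_h5(path: str | Path) -> tuple[list[ComplexFrameSequence], dict]:
    """Read slice sequences from :func:`save_frames_h5` output."""
    with h5py.File(path, "r") as h5:
        stack = h5["frames"][...]
        meta = h5["meta"]
        optics = _read_optics(meta)
        positions = meta["slice_positions_um"][...]
        starts = meta["start_times_s"][...]
        per_slice = json.loads(meta.attrs.get("per_slice_meta", "[]"))
        truth = {}
        if "truth" in h5:
            truth = {k: h5["truth"][k][...] for k in h5["truth"]}
    n_t = stack.shape[1]
    seqs = []
    for i in range(stack.shape[0]):
        m = per_slice[i] if i < len(per_slice) else {}
        seqs.append(
            ComplexFrameSequence(
                frames=stack[i],
                optics=optics,
                slice_position_um=float(positions[i]),
                timestamps_s=starts[i] + np.arange(n_t) / optics.b_scan_rate_hz,
                meta=m,
            )
        )
    return seqs, truth


def save_volume_h5(path: str | Path, vol: Volume4D) -> None:
    """Write a Volume4D: ``/structural``, ``/velocity``, ``/meta``."""
    with h5py.File(Path(path), "w") as h5:
        h5.create_dataset("structural", data=vol.structural.astype(np.float32),
                          compression="gzip", compression_opts=1)
        h5.create_dataset("velocity", data=vol.velocity_mm_s.astype(np.float32),
                          compression="gzip", compression_opts=1)
        meta = h5.create_group("meta")
        _write_optics(meta, vol.optics)
        meta.attrs["volume_rate_hz"] = vol.volume_rate_hz
        meta.attrs["period_s"] = vol.period_s
        meta.attrs["phase_count"] = vol.phase_count
        meta.create_dataset("slice_positions_um", data=vol.slice_positions_um)
        meta.attrs["extra"] = json.dumps(
            {k: v for k, v in vol.meta.items() if not isinstance(v, np.ndarray)}
        )


def load_volume_h5(path: str | Path) -> Volume4D:
    with h5py.File(Path(path), "r") as h5:
        meta = h5["meta"]
        vol = Volume4D(
            structural=h5["structural"][...].astype(float),
            velocity_mm_s=h5["velocity"][...].astype(float),
            volume_rate_hz=float(meta.attrs["volume_rate_hz"]),
            period_s=float(meta.attrs["period_s"]),
            phase_count=int(meta.attrs["phase_count"]),
            slice_positions_um=meta["slice_positions_um"][...],
            optics=_read_optics(meta),
            meta=json.loads(meta.attrs.get("extra", "{}")),
        )
    return vol


def export_structural_tiff(path: str | Path, vol: Volume4D, slice_index: int | None = None) -> None:
    """Export the structural channel as a multipage TIFF for inspection.

    One page per phase; either a single slice or a mid-volume slice.
    """
    import tifffile

    i = slice_index if slice_index is not None else vol.structural.shape[1] // 2
    stack = vol.structural[:, i].astype(np.float32)
    tifffile.imwrite(Path(path), stack)


def load_mask_stack(path: str | Path) -> list[np.ndarray]:
    """Read a multipage TIFF of per-phase lumen label masks (nonzero = lumen)."""
    import tifffile

    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return [a > 0 for a in arr]
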