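"""Readers and writers for the pipeline's on-disk formats.

Volumes and label maps travel as NIfTI (single file, explicit spacing),
observation logs / fiducials / signals / area tables as CSV, US frames
and overlays as PNG, transforms and results as JSON.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .geometry import Point3
from .hu_segmentation import CTVolume, LabelMap

__all__ = [
    "read_ct_volume",
    "write_ct_volume",
    "read_label_map",
    "write_label_map",
    "read_us_frame",
    "write_us_frame",
    "write_overlay_png",
    "write_frame_sequence",
    "read_frame_sequence",
    "FormatError",
]

logger = logging.getLogger("ctus_fusion")


class FormatError(ValueError):
    """Malformed or unreadable image file."""


def _affine(spacing, origin: Point3) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin.as_array()
    return aff


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple, Point3]:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: missing or invalid voxel spacing {zooms}")
    if max(zooms) / min(zooms) > 1.001:
        logger.warning("%s: anisotropic voxels %s", path, zooms)
    origin = Point3(*np.asarray(img.affine[:3, 3], dtype=float), "C")
    return data, tuple(float(z) for z in zooms), origin


def read_ct_volume(path: str | Path) -> CTVolume:
    """Load a HU volume from NIfTI; fails loudly on missing spacing."""
    data, spacing, origin = _load_nifti(path)
    return CTVolume(data.astype(float), spacing, origin)


def write_ct_volume(path: str | Path, volume: CTVolume) -> None:
    img = nib.Nifti1Image(
        volume.voxels.astype(np.float32), _affine(volume.spacing, volume.origin)
    )
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_label_map(path: str | Path) -> LabelMap:
    data, spacing, origin = _load_nifti(path)
    return LabelMap(np.rint(data).astype(np.uint8), spacing, origin)


def write_label_map(path: str | Path, labels: LabelMap) -> None:
    img = nib.Nifti1Image(
        labels.labels.astype(np.uint8), _affine(labels.spacing, labels.origin)
    )
    img.header.set_zooms(labels.spacing)
    nib.save(img, str(path))


def read_us_frame(path: str | Path) -> np.ndarray:
    """Load one grayscale US frame as a 2-D uint8 array."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("L"))
    except Exception as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc


def write_us_frame(path: str | Path, frame: np.ndarray) -> None:
    Image.fromarray(np.asarray(frame, dtype=np.uint8), mode="L").save(path)


def write_overlay_png(path: str | Path, overlay: np.ndarray) -> None:
    Image.fromarray(np.asarray(overlay, dtype=np.uint8), mode="RGB").save(path)


def write_frame_sequence(
    directory: str | Path, frames, timestamps, prefix: str = "frame"
) -> None:
    """Numbered grayscale PNGs plus a CSV timestamp index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "index.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "timestamp"])
        for i, (frame, t) in enumerate(zip(frames, timestamps)):
            name = f"{prefix}_{i:05d}.png"
            write_us_frame(directory / name, frame)
            writer.writerow([name, repr(float(t))])


def read_frame_sequence(directory: str | Path):
    """Load a numbered PNG sequence via its CSV index.

    Returns (frames, timestamps).
    """
    directory = Path(directory)
    frames, timestamps = [], []
    with open(directory / "index.csv", newline="") as fh:
        for rec in csv.DictReader(fh):
            frames.append(read_us_frame(directory / rec["filename"]))
            timestamps.append(float(rec["timestamp"]))
    return frames, np.array(timestamps)
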