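"""Volume and projection I/O.

Interchange format is 32-bit float multipage TIFF plus a YAML sidecar
(`<name>.yaml`) carrying voxel size, contrast convention and provenance.
Round trips are bit-identical, including the voxel size.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .recon import ReconVolume


class VolumeFormatError(RuntimeError):
    pass


def sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".yaml")


def write_volume(path, volume, voxel_m: float | None = None,
                 meta: dict | None = None) -> Path:
    """Write a volume (ReconVolume or array) as float32 multipage TIFF."""
    path = Path(path)
    if isinstance(volume, ReconVolume):
        values = volume.values
        side = {"voxel_m": float(volume.voxel_m),
                "contrast_convention": volume.contrast_convention,
                "provenance": _plain(volume.provenance)}
    else:
        values = np.asarray(volume)
        side = {"voxel_m": float(voxel_m if voxel_m is not None else 1.0),
                "contrast_convention": "phase", "provenance": {}}
    if meta:
        side.update(_plain(meta))
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, values.astype(np.float32),
                     photometric="minisblack")
    sidecar_path(path).write_text(yaml.safe_dump(side, sort_keys=True))
    return path


def read_volume(path) -> ReconVolume:
    """Read a multipage float32 TIFF written by :func:`write_volume`.

    A missing sidecar falls back to defaults with a warning; a corrupt or
    inconsistent page raises naming the slice.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            pages = tf.pages
            arrs = []
            shape0 = dtype0 = None
            for i in range(len(pages)):
                try:
                    a = pages[i].asarray()
                except Exception as exc:
                    raise VolumeFormatError(
                        f"corrupt page/slice {i} in {path}") from exc
                if shape0 is None:
                    shape0, dtype0 = a.shape, a.dtype
                elif a.shape != shape0 or a.dtype != dtype0:
                    raise VolumeFormatError(
                        f"slice {i} of {path} has shape {a.shape}/{a.dtype}, "
                        f"expected {shape0}/{dtype0}")
                arrs.append(a)
    except tifffile.TiffFileError as exc:
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    values = np.stack(arrs) if len(arrs) > 1 else arrs[0]
    sp = sidecar_path(path)
    if sp.exists():
        side = yaml.safe_load(sp.read_text()) or {}
    else:
        warnings.warn(f"no sidecar for {path}; applying defaults",
                      RuntimeWarning, stacklevel=2)
        side = {}
    return ReconVolume(values, float(side.get("voxel_m", 1.0)),
                       side.get("contrast_convention", "phase"),
                       side.get("provenance", {}) or {})


def _plain(obj):
    """Recursively convert numpy scalars/arrays to YAML-safe types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
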