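"""Projection preprocessing: flatfield correction and ring removal.

Plain flatfielding divides (projection - dark) by (flat - dark).  When the
illumination drifts between flat sessions, a PCA model of the flat stack is
fitted instead: the mean flat plus the leading principal components span
the illumination subspace, and per-projection coefficients are estimated by
least squares on a sample-free margin band at the detector edges, so the
synthesized flat matches the actual illumination of each frame.

Ring artifacts (miscalibrated detector columns) are removed in sinogram
space by subtracting, per detector column, the difference between the
angle-averaged profile and its moving-median smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class CorrectionError(RuntimeError):
    pass


@dataclass
class CorrectionReport:
    method: str
    residual_rms: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_components: int = 0
    n_invalid_pixels: int = 0
    session_map: dict = field(default_factory=dict)


def flatfield_divide(projection: np.ndarray, flat: np.ndarray,
                     dark: np.ndarray | float = 0.0,
                     eps: float = 1e-6, max_invalid_fraction: float = 0.01,
                     strict: bool = False):
    """(projection - dark) / (flat - dark), guarding degenerate pixels.

    Pixels where flat - dark <= eps are set to 1 and counted; more than
    `max_invalid_fraction` of them raises (strict) or warns.
    """
    projection = np.asarray(projection, dtype=float)
    flat = np.asarray(flat, dtype=float)
    if projection.shape != flat.shape:
        raise ValueError("projection and flat shapes differ")
    denom = flat - dark
    bad = denom <= eps
    n_bad = int(bad.sum())
    if n_bad:
        frac = n_bad / denom.size
        msg = f"{n_bad} pixels ({frac:.2%}) with flat-dark <= {eps}"
        if frac > max_invalid_fraction:
            if strict:
                raise CorrectionError(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
    out = np.ones_like(projection)
    good = ~bad
    out[good] = (projection[good] - (dark[good] if np.ndim(dark) else dark)) / denom[good]
    report = CorrectionReport(method="divide", n_invalid_pixels=n_bad)
    return out, report


def nearest_flat_assign(projection_times, flat_times) -> dict[int, int]:
    """Map each projection to the flat session nearest in time/index.

    Ties go to the earlier session.  Returns {projection index -> session
    index into flat_times}.
    """
    flat_times = np.asarray(flat_times, dtype=float)
    if flat_times.size == 0:
        raise CorrectionError("no flat sessions available")
    mapping = {}
    for i, t in enumerate(np.asarray(projection_times, dtype=float)):
        d = np.abs(flat_times - t)
        mapping[i] = int(np.argmin(d))  # argmin takes the first == earlier on ties
    return mapping


def _margin_mask(shape: tuple[int, int], margin_fraction: float) -> np.ndarray:
    h, w = shape
    mh = int(round(margin_fraction * h))
    mw = int(round(margin_fraction * w))
    if mh == 0 and mw == 0:
        raise CorrectionError("margin band is empty")
    mask = np.zeros(shape, dtype=bool)
    mask[:mh, :] = mask[h - mh:, :] = True
    mask[:, :mw] = mask[:, w - mw:] = True
    return mask


def pca_flatfield_correct(projections: np.ndarray, flats: np.ndarray,
                          n_components: int = 3, margin_fraction: float = 0.05):
    """Dynamic flatfield correction with a PCA illumination model.

    Returns (normalized stack, CorrectionReport).  With n_components = 0
    this is exactly division by the mean flat.
    """
    projections = np.atleast_3d(np.asarray(projections, dtype=float))
    if projections.ndim == 2:
        projections = projections[None]
    flats = np.asarray(flats, dtype=float)
    n_flats = flats.shape[0]
    if n_flats < n_components + 1:
        raise CorrectionError(
            f"need at least n_components+1 = {n_components + 1} flats, got {n_flats}"
        )
    shape = flats.shape[1:]
    mean_flat = flats.mean(axis=0)
    comps = np.empty((0, *shape))
    if n_components > 0:
        x = (flats - mean_flat).reshape(n_flats, -1)
        # SVD of the centred flat stack; rows of vt are the eigen-flats
        _, s, vt = np.linalg.svd(x, full_matrices=False)
        rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
        if rank < n_components:
            warnings.warn(
                f"flat stack rank {rank} < requested {n_components} components",
                RuntimeWarning, stacklevel=2)
            n_components = rank
        comps = vt[:n_components].reshape(n_components, *shape)

    mask = _margin_mask(shape, margin_fraction)
    a = np.column_stack([c[mask] for c in comps]) if n_components else None
    mf_m = mean_flat[mask]

    out = np.empty_like(projections)
    rms = np.empty(projections.shape[0])
    for i, proj in enumerate(projections):
        synth = mean_flat
        if n_components:
            b = proj[mask] - mf_m
            coef, *_ = np.linalg.lstsq(a, b, rcond=None)
            synth = mean_flat + np.tensordot(coef, comps, axes=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            norm = np.where(synth > 0, proj / synth, 1.0)
        out[i] = norm
        rms[i] = np.sqrt(np.mean((proj[mask] - synth[mask]) ** 2))
    report = CorrectionReport(method="pca", residual_rms=rms,
                              n_components=n_components)
    return out, report


def reference_to_margin(image: np.ndarray, n_rows: int = 3) -> np.ndarray:
    """Subtract the mean of the top/bottom sample-free detector rows.

    Retrieved phase maps carry an arbitrary offset (the zero-frequency
    component of the contrast transfer is weak); referencing each map to a
    band of rows the sample never crosses pins the offset to the embedding
    medium, which is also what makes the sinogram consistent with a
    compactly supported reconstruction.
    """
    image = np.asarray(image, dtype=float)
    band = np.concatenate([image[:n_rows], image[-n_rows:]])
    return image - band.mean()


def remove_rings(sinogram: np.ndarray, kernel_width: int = 9) -> np.ndarray:
    """Suppress ring artifacts in an (angle, detector-column) sinogram.

    The angle-averaged column profile is smoothed with a moving median of
    width `kernel_width`; the raw-minus-smooth difference is the per-column
    offset and is subtracted.  The sinogram mean is preserved.
    """
    sinogram = np.asarray(sinogram, dtype=float)
    n_det = sinogram.shape[-1]
    if kernel_width > n_det:
        raise ValueError(f"kernel width {kernel_width} exceeds detector size {n_det}")
    profile = sinogram.mean(axis=0)
    smooth = ndimage.median_filter(profile, size=kernel_width, mode="nearest")
    offsets = profile - smooth
    offsets -= offsets.mean()      # keep the global mean untouched
    return sinogram - offsets
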