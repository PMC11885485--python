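"""Tomographic reconstruction.

Parallel-beam slices are reconstructed by filtered backprojection (ramp
filter, linear interpolation).  Cone-beam scans over a full circle use the
Feldkamp-Davis-Kress (FDK) algorithm on a virtual detector through the
rotation axis; in the limit of vanishing cone angle FDK reduces to
slice-wise FBP.  Cone-beam holograms are first reduced to an effective
parallel geometry by the Fresnel scaling theorem (reinterpret the images on
the dx_eff grid with propagation distance z_eff = z12/M), which is why all
phase-retrieval filters only ever see effective Fresnel numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import iradon

from .geometry import AcquisitionGeometry, BeamType, GeometryError
from .forward import ProjectionSet


@dataclass
class ReconVolume:
    """Reconstructed scalar field with voxel size and contrast convention."""

    values: np.ndarray
    voxel_m: float
    contrast_convention: str = "phase"     # "phase" or "attenuation"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite voxels in reconstruction")

    @property
    def shape(self):
        return self.values.shape


def fresnel_rescale_to_parallel(pset: ProjectionSet) -> ProjectionSet:
    """Reinterpret a cone-beam recording as an effective parallel one.

    The Fresnel scaling theorem maps a cone-beam hologram at (dx, z12, M)
    onto the parallel hologram sampled at dx_eff = dx/M propagated over
    z_eff = z12/M.  Pixel values are untouched; only the geometry is
    rewritten.  Parallel input (M = 1) is returned unchanged.
    """
    g = pset.geometry
    if g.beam_type is BeamType.parallel or g.magnification == 1.0:
        return pset
    if not g.magnification > 0:
        raise GeometryError("missing magnification")
    eff = AcquisitionGeometry(
        energy_keV=g.energy_keV, wavelength_m=g.wavelength_m,
        dx_m=g.dx_eff_m / g.binning, binning=g.binning,
        z01_m=g.z01_m, z12_m=g.z_eff_m, z02_m=g.z01_m + g.z_eff_m,
        magnification=1.0, dx_eff_m=g.dx_eff_m, z_eff_m=g.z_eff_m,
        fresnel_number=g.fresnel_number, beam_type=BeamType.parallel,
    )
    return replace(pset, geometry=eff)


def fbp_parallel(sinograms: np.ndarray, angles_deg, filter_name: str = "ramp",
                 voxel_m: float = 1.0, interpolation: str = "linear",
                 contrast_convention: str = "phase") -> ReconVolume:
    """Filtered backprojection of parallel-beam sinograms.

    `sinograms` has shape (n_slices, n_angles, n_detector) or
    (n_angles, n_detector) for a single slice; values are line integrals in
    units of value*pixel, recorded in the convention of
    :func:`xpct.forward.project_optical` (object rotated by the angle about
    its (n//2, n//2) centre, integrated along x, detector = y index), whose
    inverse this function is.  360-degree data is handled by the
    backprojection normalization (conjugate rays average).  The operator is
    linear.
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.size < 2:
        raise ValueError("need at least 2 projection angles")
    sinos = np.asarray(sinograms, dtype=float)
    single = sinos.ndim == 2
    if single:
        sinos = sinos[None]
    n_det = sinos.shape[-1]
    out = np.empty((sinos.shape[0], n_det, n_det))
    for i, s in enumerate(sinos):
        out[i] = iradon(s.T, theta=angles_deg - 90.0, filter_name=filter_name,
                        interpolation=interpolation, circle=True,
                        output_size=n_det)
    # iradon normalizes assuming theta spans 180 deg; a 360 deg scan covers
    # each ray twice, which the pi/(2N) weight already averages correctly.
    values = out[0] if single else out
    return ReconVolume(values, voxel_m, contrast_convention,
                       provenance={"method": "fbp_parallel",
                                   "filter": filter_name,
                                   "interpolation": interpolation,
                                   "n_angles": int(angles_deg.size)})


def _ramp_filter_rows(proj: np.ndarray) -> np.ndarray:
    """Ramp-filter each detector row (last axis) of a projection.

    Uses the band-limited spatial ramp kernel (h[0] = 1/4,
    h[n odd] = -1/(pi n)^2, h[n even] = 0), whose DFT is the standard
    discrete ramp; this matches the filter of the parallel-beam FBP so the
    two reconstructions agree in the small-cone limit.
    """
    n = proj.shape[-1]
    nfft = 2 * int(2 ** np.ceil(np.log2(max(n, 2))))
    k = np.concatenate([np.arange(nfft // 2 + 1), np.arange(nfft // 2 - 1, 0, -1)])
    h = np.zeros(nfft)
    h[0] = 0.25
    odd = k % 2 == 1
    h[odd] = -1.0 / (np.pi * k[odd]) ** 2
    filt = 2.0 * np.real(np.fft.fft(h))
    spec = np.fft.fft(proj, n=nfft, axis=-1) * filt / 2.0
    return np.fft.ifft(spec, axis=-1).real[..., :n]


def fdk_cone(projections: np.ndarray, angles_deg, src_dist_vox: float,
             voxel_m: float = 1.0, vol_shape=None,
             contrast_convention: str = "attenuation") -> ReconVolume:
    """Feldkamp-Davis-Kress reconstruction of a circular cone-beam scan.

    `projections` has shape (n_angles, H, W) sampled on a virtual detector
    through the rotation axis with pixel = voxel; `src_dist_vox` is the
    source-to-axis distance in voxel units.  Requires (close to) full
    360-degree coverage; the algorithm is exact on the central plane for
    small cone angles and reduces to FBP as src_dist -> infinity.
    """
    angles = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if angles.size < 2:
        raise ValueError("need at least 2 projection angles")
    span = float(np.max(angles) - np.min(angles))
    if span < np.deg2rad(300.0):
        raise ValueError(
            "fdk_cone requires a (near) full-circle scan; "
            f"got span {np.rad2deg(span):.1f} deg")
    projections = np.asarray(projections, dtype=float)
    n_ang, h, w = projections.shape
    if vol_shape is None:
        vol_shape = (h, w, w)
    nz, ny, nx = vol_shape
    R = float(src_dist_vox)

    u = np.arange(w, dtype=float) - w // 2
    v = np.arange(h, dtype=float) - h // 2
    uu, vv = np.meshgrid(u, v)
    cos_w = R / np.sqrt(R**2 + uu**2 + vv**2)       # FDK pre-weight

    zs = np.arange(nz, dtype=float) - nz // 2
    ys = np.arange(ny, dtype=float) - ny // 2
    xs = np.arange(nx, dtype=float) - nx // 2
    zg, yg, xg = np.meshgrid(zs, ys, xs, indexing="ij")

    vol = np.zeros(vol_shape)
    d_ang = span / max(n_ang - 1, 1)
    for ia, ang in enumerate(angles):
        p = _ramp_filter_rows(projections[ia] * cos_w)
        # in-plane coordinates: s along detector u, d toward the source
        s = xg * np.cos(ang) + yg * np.sin(ang)
        d = -xg * np.sin(ang) + yg * np.cos(ang)
        U = R / (R - d)
        up = s * U
        vp = zg * U
        iu = up + w // 2
        iv = vp + h // 2
        iu0 = np.clip(np.floor(iu).astype(int), 0, w - 2)
        iv0 = np.clip(np.floor(iv).astype(int), 0, h - 2)
        fu = np.clip(iu - iu0, 0.0, 1.0)
        fv = np.clip(iv - iv0, 0.0, 1.0)
        val = ((1 - fv) * (1 - fu) * p[iv0, iu0]
               + (1 - fv) * fu * p[iv0, iu0 + 1]
               + fv * (1 - fu) * p[iv0 + 1, iu0]
               + fv * fu * p[iv0 + 1, iu0 + 1])
        inside = (iu >= 0) & (iu <= w - 1) & (iv >= 0) & (iv <= h - 1)
        vol += np.where(inside, U**2 * val, 0.0) * d_ang
    vol *= 0.5     # full-circle coverage counts every ray twice
    return ReconVolume(vol, voxel_m, contrast_convention,
                       provenance={"method": "fdk_cone", "src_dist_vox": R,
                                   "n_angles": n_ang})


def bin_volume(volume: ReconVolume | np.ndarray, k: int) -> ReconVolume:
    """k-fold isotropic block-mean binning; voxel size scales by k.

    Trailing partial blocks are dropped; when every dimension divides k the
    global mean is preserved exactly.
    """
    if k < 1 or int(k) != k:
        raise ValueError("binning factor must be a positive integer")
    if isinstance(volume, ReconVolume):
        vals, voxel_m, conv, prov = (volume.values, volume.voxel_m,
                                     volume.contrast_convention,
                                     dict(volume.provenance))
    else:
        vals, voxel_m, conv, prov = np.asarray(volume), 1.0, "phase", {}
    if any(s < k for s in vals.shape):
        raise ValueError(f"bin factor {k} exceeds volume shape {vals.shape}")
    if k == 1:
        return ReconVolume(vals.copy(), voxel_m, conv, prov)
    nz, ny, nx = (s // k for s in vals.shape)
    trimmed = vals[:nz * k, :ny * k, :nx * k]
    binned = trimmed.reshape(nz, k, ny, k, nx, k).mean(axis=(1, 3, 5))
    prov["binned"] = prov.get("binned", 1) * k
    return ReconVolume(binned, voxel_m * k, conv, prov)
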