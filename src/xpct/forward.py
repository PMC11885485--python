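"""Holographic forward model.

The projection approximation turns the phantom's 3D optical constants into
a 2D exit wave behind the object,

    phi(x, y) = -(2*pi/lambda) * integral of delta along the beam,
    B(x, y)   =  (2*pi/lambda) * integral of beta  along the beam,

with complex transmission exp(-B + i*phi).  Free-space propagation to the
detector is modelled with the paraxial single-FFT transfer function written
in Fresnel-number units,

    I = | IFT[ FT[exp(-B + i*phi)] * exp(-i*pi*(fx^2 + fy^2)/F) ] |^2,

where fx, fy are spatial frequencies in cycles/pixel, so the only optical
parameter the propagator needs is the Fresnel number of the (effective)
pixel.  Cone-beam recordings are reduced to this parallel form by the
Fresnel scaling theorem: simulate on the dx_eff grid with the effective
distance z_eff = z12/M.

Detection multiplies by an illumination field, scales to a photon budget,
adds a dark offset and Poisson-samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import AcquisitionGeometry, BeamType


@dataclass
class ExitWave:
    """Projected phase and absorption maps (detector rows = z, cols = y)."""

    phase_map: np.ndarray
    absorption_map: np.ndarray
    pixel_m: float
    geometry: AcquisitionGeometry | None = None

    def __post_init__(self):
        if self.phase_map.shape != self.absorption_map.shape:
            raise ValueError("phase and absorption maps must share shape")

    @property
    def transmission(self) -> np.ndarray:
        return np.exp(-self.absorption_map + 1j * self.phase_map)


def rotate_volume_z(vol: np.ndarray, angle_deg: float, cval: float = 0.0) -> np.ndarray:
    """Rotate a (z, y, x) volume about the z axis by `angle_deg`.

    The rotation centre is (n//2, n//2) in the (y, x) plane, matching the
    centre convention of the filtered-backprojection inverse; trilinear
    interpolation, out-of-grid voxels read `cval`.
    """
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    m = np.array([[1.0, 0.0, 0.0],
                  [0.0, c, -s],
                  [0.0, s, c]])
    centre = np.array([0.0, vol.shape[1] // 2, vol.shape[2] // 2])
    off = centre - m @ centre
    return ndimage.affine_transform(vol, m, offset=off, order=1,
                                    mode="constant", cval=cval)


def project_optical(phantom, angle_deg: float, wavelength_m: float,
                    geometry: AcquisitionGeometry | None = None) -> ExitWave:
    """Exit wave of the phantom viewed at one rotation angle.

    The phantom is rotated about the vertical (z) axis by `angle_deg`
    (trilinear interpolation, voxels outside the grid read as the background
    medium) and integrated along the x axis; the detector coordinate is the
    y index of the rotated grid.
    """
    k = 2 * np.pi / wavelength_m
    bg_delta = float(phantom.delta_grid[0, 0, 0])
    bg_beta = float(phantom.beta_grid[0, 0, 0])
    if angle_deg % 360.0 == 0.0:
        d = phantom.delta_grid.astype(np.float64)
        b = phantom.beta_grid.astype(np.float64)
    else:
        d = rotate_volume_z(phantom.delta_grid.astype(np.float64), angle_deg,
                            cval=bg_delta)
        b = rotate_volume_z(phantom.beta_grid.astype(np.float64), angle_deg,
                            cval=bg_beta)
    path = phantom.voxel_m
    phi = -k * d.sum(axis=2) * path
    absb = k * b.sum(axis=2) * path
    return ExitWave(phi, absb, phantom.voxel_m, geometry)


def fresnel_kernel(shape: tuple[int, int], fresnel_number: float) -> np.ndarray:
    """Paraxial transfer function exp(-i*pi*(fx^2+fy^2)/F) on an FFT grid."""
    if not np.isfinite(fresnel_number) or fresnel_number <= 0:
        raise ValueError(f"Fresnel number must be positive, got {fresnel_number}")
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    chi = np.pi * (fy**2 + fx**2) / fresnel_number
    return np.exp(-1j * chi)


def fresnel_propagate(exit_wave: ExitWave | tuple, fresnel_number: float,
                      pad: int = 2) -> np.ndarray:
    """Propagate an exit wave and return the intensity image.

    `pad` is the per-axis padding factor (reflective) suppressing FFT
    wrap-around; `pad=1` means periodic propagation (exactly unitary for
    pure-phase objects).  F = inf returns the contact image exp(-2B).
    """
    if isinstance(exit_wave, ExitWave):
        psi = exit_wave.transmission
    else:
        phase, absorption = exit_wave
        psi = np.exp(-np.asarray(absorption) + 1j * np.asarray(phase))
    if not np.all(np.isfinite(psi)):
        raise ValueError("non-finite exit wave")
    if np.isinf(fresnel_number):
        return np.abs(psi) ** 2
    h, w = psi.shape
    if pad > 1:
        py, px = (pad - 1) * h // 2, (pad - 1) * w // 2
        psi = np.pad(psi, ((py, py), (px, px)), mode="reflect")
    kern = fresnel_kernel(psi.shape, fresnel_number)
    out = np.fft.ifft2(np.fft.fft2(psi) * kern)
    intensity = np.abs(out) ** 2
    if pad > 1:
        intensity = intensity[py:py + h, px:px + w]
    return intensity


# ---------------------------------------------------------------------------
# Tomographic acquisition


class PlanError(ValueError):
    pass


@dataclass
class AcquisitionPlan:
    """What to record: angles, defocus distances, tiles, photons, flats.

    `distances_m` are sample-to-detector values z12; each maps to its own
    Fresnel number through the base geometry (z01 fixed for a cone beam).
    Tiles are lateral sample offsets in voxels (z, y); tiles sharing a
    `plane_of_tile` entry share one flatfield session, mirroring the
    record-flats-before-each-plane protocol of stitched scans.
    """

    geometry: AcquisitionGeometry
    angles_deg: np.ndarray
    distances_m: tuple[float, ...] | None = None
    tile_offsets: tuple[tuple[int, int], ...] = ((0, 0),)
    plane_of_tile: tuple[int, ...] | None = None
    photons: float | None = None
    illumination: np.ndarray | None = None
    dark_offset: float = 0.0
    n_flats: int = 4
    pad: int = 2
    seed: int = 0

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.size == 0:
            raise PlanError("empty angle list")
        if self.distances_m is None:
            self.distances_m = (self.geometry.z12_m,)
        if any(d <= 0 for d in self.distances_m):
            raise PlanError("distances must be positive")
        if self.plane_of_tile is None:
            self.plane_of_tile = tuple(range(len(self.tile_offsets)))
        if len(self.plane_of_tile) != len(self.tile_offsets):
            raise PlanError("plane_of_tile must match tile_offsets")

    def fresnel_numbers(self, pixel_m: float) -> np.ndarray:
        """Per-distance Fresnel numbers on the simulation grid."""
        g = self.geometry
        out = []
        for z12 in self.distances_m:
            gd = g.with_distance(z12)
            out.append(pixel_m**2 / (gd.z_eff_m * gd.wavelength_m))
        return np.asarray(out)


@dataclass
class ProjectionSet:
    """Recorded intensities indexed (angle, distance, tile) with references."""

    intensities: np.ndarray          # (n_angles, n_dist, n_tiles, H, W)
    angles_deg: np.ndarray
    distances_m: tuple[float, ...]
    fresnel_numbers: np.ndarray
    flats: dict[int, np.ndarray]     # session -> (n_flats, H, W)
    darks: dict[int, np.ndarray]
    session_of_tile: tuple[int, ...]
    geometry: AcquisitionGeometry
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities")


def acquire_tomogram(phantom, plan: AcquisitionPlan) -> ProjectionSet:
    """Simulate the full recording described by `plan`.

    Noise-free with unit illumination and zero dark offset, the images are
    exactly the Fresnel-propagated exit-wave intensities.
    """
    rng = np.random.default_rng(plan.seed)
    fns = plan.fresnel_numbers(phantom.voxel_m)
    wl = plan.geometry.wavelength_m
    nz, ny, _ = phantom.shape
    n_ang, n_dist, n_tiles = len(plan.angles_deg), len(fns), len(plan.tile_offsets)
    out = np.empty((n_ang, n_dist, n_tiles, nz, ny))
    illum = plan.illumination if plan.illumination is not None else 1.0

    for it, (dz, dy) in enumerate(plan.tile_offsets):
        if (dz, dy) == (0, 0):
            ph = phantom
        else:
            ph = _shifted_phantom(phantom, dz, dy)
        for ia, ang in enumerate(plan.angles_deg):
            wave = project_optical(ph, ang, wl, plan.geometry)
            for idist, F in enumerate(fns):
                img = fresnel_propagate(wave, F, pad=plan.pad) * illum
                if plan.photons is not None:
                    img = rng.poisson(img * plan.photons).astype(np.float64)
                    img /= 1.0  # keep raw counts
                out[ia, idist, it] = img + plan.dark_offset

    flats, darks = {}, {}
    for session in sorted(set(plan.plane_of_tile)):
        base = np.broadcast_to(np.asarray(illum, dtype=float),
                               (plan.n_flats, nz, ny)).copy()
        if plan.photons is not None:
            base = rng.poisson(base * plan.photons).astype(np.float64)
        flats[session] = base + plan.dark_offset
        darks[session] = np.full((plan.n_flats, nz, ny), float(plan.dark_offset))

    return ProjectionSet(
        intensities=out, angles_deg=plan.angles_deg,
        distances_m=tuple(plan.distances_m), fresnel_numbers=fns,
        flats=flats, darks=darks, session_of_tile=tuple(plan.plane_of_tile),
        geometry=plan.geometry, seed=plan.seed,
        meta={"photons": plan.photons, "dark_offset": plan.dark_offset},
    )


def _shifted_phantom(phantom, dz: int, dy: int):
    from copy import copy
    ph = copy(phantom)
    ph.delta_grid = np.roll(phantom.delta_grid, (dz, dy), axis=(0, 1))
    ph.beta_grid = np.roll(phantom.beta_grid, (dz, dy), axis=(0, 1))
    return ph


# ---------------------------------------------------------------------------
# Analytic cone-beam projector (oracle for FDK tests)


def cone_project_spheres(centers, radii, values, src_dist: float,
                         det_shape: tuple[int, int], angles_deg,
                         det_pixel: float = 1.0) -> np.ndarray:
    """Exact cone-beam line integrals of a set of uniform spheres.

    Source on a circle of radius `src_dist` (voxel units) about the z axis,
    flat virtual detector through the rotation axis, pixel size `det_pixel`.
    The chord length of a ray through a uniform sphere is closed-form, so
    these projections are an analytic oracle independent of any voxel
    projector.  Returns (n_angles, H, W).
    """
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    values = np.asarray(values, dtype=float)
    h, w = det_shape
    v = (np.arange(h, dtype=float) - h // 2) * det_pixel
    u = (np.arange(w, dtype=float) - w // 2) * det_pixel
    uu, vv = np.meshgrid(u, v)
    out = np.zeros((len(angles_deg), h, w))
    for ia, ang in enumerate(np.deg2rad(angles_deg)):
        # source position and detector basis in (x, y, z)
        src = np.array([-src_dist * np.sin(ang), src_dist * np.cos(ang), 0.0])
        eu = np.array([np.cos(ang), np.sin(ang), 0.0])
        ev = np.array([0.0, 0.0, 1.0])
        pts = uu[..., None] * eu + vv[..., None] * ev  # detector points
        dirs = pts - src
        norm = np.linalg.norm(dirs, axis=-1, keepdims=True)
        dirs = dirs / norm
        for c, r, val in zip(centers, radii, values):
            oc = src - c
            b = np.einsum("hwk,k->hw", dirs, oc)
            disc = b**2 - (oc @ oc - r**2)
            chord = 2.0 * np.sqrt(np.clip(disc, 0.0, None))
            out[ia] += val * chord
    return out
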