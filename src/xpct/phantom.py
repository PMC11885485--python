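"""Synthetic cochlea-like phantom and structured flatfield generator.

The phantom is not an anatomical model.  It reproduces the geometric and
statistical structure that the downstream operators care about: a conical
spiral fluid channel (the scalae) wrapped around a central axis (the
modiolus), split into three sub-channels by two thin membranes, enclosed in
a bone-like shell, with a population of compact spherical blobs standing in
for spiral ganglion neuron (SGN) somata along an inner spiral path.  Every
blob is recorded in a ground-truth table (centre, radius, analytic volume,
sphericity 1), which downstream detection/morphometry tests score against.

Grids are ordered (z, y, x) with 0-based indices and voxel centres on
integer coordinates; this convention is shared by all modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .materials import material_dict

LABEL_BACKGROUND = 0
LABEL_BONE = 1
LABEL_SCALA = 2
LABEL_MEMBRANE = 3
BLOB_LABEL_START = 10


class PhantomCapacityError(RuntimeError):
    """Raised when the requested blobs cannot be placed without overlap."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could only place {achieved} of {requested} non-overlapping blobs"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cochlea phantom.

    Defaults give 2.5 spiral turns in a 256³ grid at 2 µm voxels with 200
    blobs of 6–14 µm radius, the scale at which SGN somata appear in
    sub-micron to few-micron tomograms.
    """

    shape_vox: tuple[int, int, int] = (256, 256, 256)
    voxel_m: float = 2.0e-6
    n_turns: float = 2.5
    n_blobs: int = 200
    blob_radius_mean_m: float = 10.0e-6
    blob_radius_sd_m: float = 3.0e-6
    membrane_thickness_vox: int = 2
    material_set: str = "unstained-in-methanol"
    energy_keV: float = 13.8
    seed: int = 0
    max_attempts_per_blob: int = 200

    def __post_init__(self):
        if any(s <= 0 for s in self.shape_vox):
            raise ValueError("shape must be positive")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")
        if self.blob_radius_mean_m < self.voxel_m:
            raise ValueError("blob radii must be at least one voxel")


@dataclass
class PhantomVolume:
    """delta/beta fields, material labels and blob ground truth."""

    delta_grid: np.ndarray
    beta_grid: np.ndarray
    label_grid: np.ndarray
    voxel_m: float
    truth_blobs: pd.DataFrame
    materials: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.delta_grid.shape


def _paint_ball(grid: np.ndarray, center: np.ndarray, radius: float, value: int,
                only_where: int | None = None) -> None:
    """Set grid voxels within `radius` of `center` to `value` (in place)."""
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, grid.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    mask = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius**2
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if only_where is not None:
        mask = mask & (sub == only_where)
    sub[mask] = value


def _ball_region_labels(grid: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, grid.shape)
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    mask = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius**2
    return grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][mask]


def _spiral_path(spec: PhantomSpec, n_samples: int):
    """Conical spiral centreline and local channel/shell radii, in voxels.

    Returns (points (n,3) in (z,y,x), channel radius per sample).
    """
    nz, ny, nx = spec.shape_vox
    t = np.linspace(0.0, 2 * np.pi * spec.n_turns, n_samples)
    frac = t / t[-1] if t[-1] > 0 else t
    r_outer = 0.33 * min(ny, nx)
    r_inner = 0.14 * min(ny, nx)
    radius = r_outer + (r_inner - r_outer) * frac
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    z = 0.16 * nz + (0.68 * nz) * frac
    y = cy + radius * np.sin(t)
    x = cx + radius * np.cos(t)
    r_ch = (0.085 - 0.035 * frac) * min(ny, nx)
    return np.stack([z, y, x], axis=1), r_ch


def generate_cochlea_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Build the phantom volume deterministically from spec + seed."""
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape_vox
    labels = np.zeros(spec.shape_vox, dtype=np.int32)

    # path sampling fine enough that consecutive balls overlap heavily
    path_len_est = 2 * np.pi * spec.n_turns * 0.25 * min(ny, nx)
    n_samples = max(64, int(path_len_est * 2))
    points, r_ch = _spiral_path(spec, n_samples)
    shell = max(2.0, 0.015 * min(ny, nx))

    # 1) bone shell, 2) carve the fluid lumen
    for p, rc in zip(points, r_ch):
        _paint_ball(labels, p, rc + shell, LABEL_BONE)
    for p, rc in zip(points, r_ch):
        _paint_ball(labels, p, rc, LABEL_SCALA)

    # 3) two thin membranes splitting each cross-section into three scalae:
    # horizontal sheets offset above/below the local centreline.  Each lumen
    # voxel is assigned to its single nearest centreline sample so the
    # sheets cannot stack where painted spheres overlap.
    from scipy.spatial import cKDTree
    mt = spec.membrane_thickness_vox
    half = (mt - 1) / 2.0
    lumen_idx = np.argwhere(labels == LABEL_SCALA)
    if lumen_idx.size:
        tree = cKDTree(points)
        _, nearest = tree.query(lumen_idx.astype(float), workers=-1)
        dz = lumen_idx[:, 0] - points[nearest, 0]
        off = r_ch[nearest] / 3.0
        sheet = (np.abs(dz - off) <= half) | (np.abs(dz + off) <= half)
        sel = lumen_idx[sheet]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = LABEL_MEMBRANE

    # 4) blobs in the modiolar region inside the spiral tube: sampled along
    # the path at a radial fraction small enough to clear the bone shell
    blob_rows = []
    centers: list[np.ndarray] = []
    radii: list[float] = []
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    spiral_r = np.hypot(points[:, 1] - cy, points[:, 2] - cx)
    pitch = 0.68 * nz / max(spec.n_turns, 0.5)    # z rise per turn
    for i in range(spec.n_blobs):
        placed = False
        for _ in range(spec.max_attempts_per_blob):
            k = rng.integers(0, len(points))
            # soma radii truncated at half the mean: SGN somata have a
            # biological size floor (no sub-5-um cell bodies at 10 um mean)
            r_m = rng.normal(spec.blob_radius_mean_m, spec.blob_radius_sd_m)
            r_m = max(r_m, spec.blob_radius_mean_m / 2.0)
            r = max(r_m / spec.voxel_m, 1.0)
            f_max = (spiral_r[k] - r_ch[k] - shell - r - 1.0) / max(spiral_r[k], 1e-9)
            if f_max <= 0.05:
                continue
            u = rng.uniform(0.05, f_max)
            c = np.array([
                points[k, 0] + rng.uniform(-pitch / 3, pitch / 3),
                cy + (points[k, 1] - cy) * u,
                cx + (points[k, 2] - cx) * u,
            ])
            if np.any(c - r < 0) or np.any(c + r >= spec.shape_vox):
                continue
            ok = True
            for cj, rj in zip(centers, radii):
                if np.linalg.norm(c - cj) < r + rj + 1.0:
                    ok = False
                    break
            if not ok:
                continue
            region = _ball_region_labels(labels, c, r)
            if region.size and np.any(region != LABEL_BACKGROUND):
                continue
            label = BLOB_LABEL_START + i
            _paint_ball(labels, c, r, label)
            centers.append(c)
            radii.append(r)
            r_phys = r * spec.voxel_m
            blob_rows.append({
                "id": label, "z": c[0], "y": c[1], "x": c[2],
                "radius_vox": r, "radius_m": r_phys,
                "volume_m3": 4.0 / 3.0 * np.pi * r_phys**3,
                "sphericity": 1.0,
            })
            placed = True
            break
        if not placed:
            raise PhantomCapacityError(spec.n_blobs, len(blob_rows))

    truth = pd.DataFrame(
        blob_rows,
        columns=["id", "z", "y", "x", "radius_vox", "radius_m",
                 "volume_m3", "sphericity"],
    )

    mats = material_dict(spec.material_set, spec.energy_keV)
    label_to_material = {
        LABEL_BACKGROUND: "background",
        LABEL_BONE: "bone",
        LABEL_SCALA: "background",   # scalae filled with the embedding fluid
        LABEL_MEMBRANE: "membrane",
    }
    delta = np.empty(spec.shape_vox, dtype=np.float32)
    beta = np.empty(spec.shape_vox, dtype=np.float32)
    for lab, mat in label_to_material.items():
        m = labels == lab
        delta[m] = mats[mat].delta
        beta[m] = mats[mat].beta
    blob_mask = labels >= BLOB_LABEL_START
    delta[blob_mask] = mats["blob"].delta
    beta[blob_mask] = mats["blob"].beta

    return PhantomVolume(delta, beta, labels, spec.voxel_m, truth,
                         materials=mats)


def generate_flatfield_stack(
    n_images: int,
    n_modes: int,
    mean_counts: float,
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
    poisson: bool = True,
    mode_amplitude: float = 0.05,
):
    """Synthetic flatfield stack with low-rank illumination drift.

    Each image is ``mean_counts`` plus a random linear combination of
    ``n_modes`` smooth low-frequency modes (unit-RMS cosine products with
    random orientation/phase), optionally Poisson-sampled.  Returns
    ``(stack, truth)`` where ``truth`` holds the modes and per-image
    coefficients.
    """
    if n_modes < 0:
        raise ValueError("n_modes must be >= 0")
    if mean_counts <= 0:
        raise ValueError("mean_counts must be positive")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    modes = np.empty((n_modes, h, w))
    for k in range(n_modes):
        fy = rng.uniform(0.3, 1.8) / h
        fx = rng.uniform(0.3, 1.8) / w
        phy, phx = rng.uniform(0, 2 * np.pi, size=2)
        m = np.cos(2 * np.pi * fy * yy + phy) * np.cos(2 * np.pi * fx * xx + phx)
        modes[k] = m / np.sqrt(np.mean(m**2))
    coeffs = rng.normal(0.0, mode_amplitude * mean_counts, size=(n_images, n_modes))
    stack = np.full((n_images, h, w), float(mean_counts))
    if n_modes:
        stack += np.einsum("ik,khw->ihw", coeffs, modes)
    np.clip(stack, 0.0, None, out=stack)
    if poisson:
        stack = rng.poisson(stack).astype(np.float64)
    truth = {"modes": modes, "coeffs": coeffs, "mean_counts": float(mean_counts)}
    return stack, truth
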