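"""Rigid stitching of overlapping ROI-tomogram tiles.

Whole-organ coverage is obtained by recording a grid of overlapping ROI
tomograms (e.g. 3x3 tiles in 4 planes = 36 tomograms) and fusing them into
one volume.  The model here is rigid translation only: pairwise offsets
between overlapping tiles are measured by normalized cross-correlation,
reconciled into globally consistent positions by least squares (anchor tile
fixed at the origin), and the tiles are fused with linear feathering whose
weights sum to one everywhere.  A k-fold binned copy of the fused volume
serves as the low-resolution overview/lookup volume.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .recon import ReconVolume, bin_volume


@dataclass
class TileLayout:
    """Grid of tiles with nominal voxel positions.

    `grid` is (nx, ny, nz); `nominal_offsets[i]` is the (z, y, x) position
    of tile i's origin in the fused frame; `tiles` are the tile volumes
    (arrays or ReconVolumes) in the same order.
    """

    grid: tuple[int, int, int]
    nominal_offsets: np.ndarray
    tiles: list
    overlap_vox: int = 8

    def __post_init__(self):
        nx, ny, nz = self.grid
        if len(self.tiles) != nx * ny * nz:
            raise ValueError(
                f"tile count {len(self.tiles)} != grid product {nx * ny * nz}")
        self.nominal_offsets = np.asarray(self.nominal_offsets, dtype=float)

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)


@dataclass
class OffsetSolution:
    pairwise: dict[tuple[int, int], tuple[np.ndarray, float]]
    global_positions: np.ndarray
    residual: float
    low_confidence: list[tuple[int, int]] = field(default_factory=list)


def _as_array(tile) -> np.ndarray:
    return tile.values if isinstance(tile, ReconVolume) else np.asarray(tile)


def estimate_offset_pair(tile_a, tile_b, nominal, search_radius: int = 5,
                         subvoxel: bool = False, score_threshold: float = 0.5):
    """Offset of tile B relative to tile A maximizing overlap correlation.

    `nominal` is the expected (z, y, x) offset of B's origin in A's frame.
    All integer offsets within `search_radius` (Chebyshev) of nominal are
    scored by normalized cross-correlation of the mean-subtracted overlap;
    ties break toward the nominal offset.  Returns (offset, score,
    low_confidence).
    """
    a, b = _as_array(tile_a), _as_array(tile_b)
    nominal = np.asarray(nominal, dtype=int)
    best_off, best_score = nominal.astype(float), -np.inf
    r = int(search_radius)
    for dz, dy, dx in itertools.product(range(-r, r + 1), repeat=3):
        off = nominal + (dz, dy, dx)
        ov_a, ov_b = _overlap_views(a, b, off)
        if ov_a is None or ov_a.size < 8**3:
            continue
        score = _ncc(ov_a, ov_b)
        better = score > best_score + 1e-12
        tie = abs(score - best_score) <= 1e-12 and (
            np.abs(off - nominal).sum() < np.abs(best_off - nominal).sum())
        if better or tie:
            best_off, best_score = off.astype(float), score
    if not np.isfinite(best_score):
        raise ValueError("no valid overlap within the search radius")
    if subvoxel:
        best_off = _parabolic_refine(a, b, best_off.astype(int))
    low_conf = best_score < score_threshold
    return best_off, float(best_score), low_conf


def _overlap_views(a: np.ndarray, b: np.ndarray, off):
    """Views of A and B over their overlap when B's origin sits at `off`."""
    off = np.asarray(off, dtype=int)
    lo = np.maximum(off, 0)
    hi = np.minimum(np.asarray(a.shape), off + np.asarray(b.shape))
    if np.any(hi - lo <= 0):
        return None, None
    sa = tuple(slice(l, h) for l, h in zip(lo, hi))
    sb = tuple(slice(l - o, h - o) for l, h, o in zip(lo, hi, off))
    return a[sa], b[sb]


def _ncc(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0   # featureless overlap: no evidence
    return float(np.vdot(x, y).real / (nx * ny))


def _parabolic_refine(a, b, off_int):
    """Per-axis 3-point parabola through the NCC peak."""
    out = off_int.astype(float)
    for ax in range(3):
        scores = []
        for d in (-1, 0, 1):
            off = off_int.copy()
            off[ax] += d
            ov_a, ov_b = _overlap_views(a, b, off)
            scores.append(_ncc(ov_a, ov_b) if ov_a is not None and ov_a.size else -1.0)
        s_m, s_0, s_p = scores
        denom = s_m - 2 * s_0 + s_p
        if denom < 0:
            out[ax] = off_int[ax] + 0.5 * (s_m - s_p) / denom
    return out


def globalize_offsets(pairwise: dict, layout: TileLayout,
                      anchor: int = 0) -> OffsetSolution:
    """Least-squares tile positions from pairwise offset measurements.

    `pairwise` maps (i, j) to (offset of j in i's frame, score).  Minimizes
    sum ||p_j - p_i - offset_ij||^2 with p_anchor = 0 and reports the
    largest per-edge residual (cycle-closure error).
    """
    n = layout.n_tiles
    if n == 1:
        return OffsetSolution({}, np.zeros((1, 3)), 0.0)
    edges = list(pairwise.items())
    if not edges:
        raise ValueError("no pairwise measurements")
    _check_connected(n, [e[0] for e in edges], anchor)
    rows = len(edges) + 1
    positions = np.zeros((n, 3))
    for axis in range(3):
        a = np.zeros((rows, n))
        b = np.zeros(rows)
        for r, ((i, j), (off, _score)) in enumerate(edges):
            a[r, j] = 1.0
            a[r, i] = -1.0
            b[r] = np.asarray(off, dtype=float)[axis]
        a[-1, anchor] = 1.0   # anchor at the origin
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        positions[:, axis] = sol - sol[anchor]
    residual = 0.0
    for (i, j), (off, _s) in edges:
        err = positions[j] - positions[i] - np.asarray(off, dtype=float)
        residual = max(residual, float(np.abs(err).max()))
    return OffsetSolution(dict(pairwise), positions, residual)


def per_edge_errors(solution: OffsetSolution) -> dict[tuple[int, int], float]:
    out = {}
    for (i, j), (off, _s) in solution.pairwise.items():
        err = (solution.global_positions[j] - solution.global_positions[i]
               - np.asarray(off, dtype=float))
        out[(i, j)] = float(np.abs(err).max())
    return out


def _check_connected(n: int, edges, anchor: int):
    adj = {i: set() for i in range(n)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen = {anchor}
    stack = [anchor]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if len(seen) != n:
        missing = sorted(set(range(n)) - seen)
        raise ValueError(f"pairwise graph disconnected; unreachable tiles {missing}")


def neighbour_pairs(grid: tuple[int, int, int]):
    """Index pairs of face-adjacent tiles in x-fastest enumeration order."""
    nx, ny, nz = grid

    def idx(ix, iy, iz):
        return (iz * ny + iy) * nx + ix

    pairs = []
    for iz, iy, ix in itertools.product(range(nz), range(ny), range(nx)):
        if ix + 1 < nx:
            pairs.append((idx(ix, iy, iz), idx(ix + 1, iy, iz)))
        if iy + 1 < ny:
            pairs.append((idx(ix, iy, iz), idx(ix, iy + 1, iz)))
        if iz + 1 < nz:
            pairs.append((idx(ix, iy, iz), idx(ix, iy, iz + 1)))
    return pairs


def solve_layout(layout: TileLayout, search_radius: int = 5) -> OffsetSolution:
    """Measure all face-neighbour offsets and globalize them."""
    pairwise = {}
    low_conf = []
    for i, j in neighbour_pairs(layout.grid):
        nominal = (layout.nominal_offsets[j] - layout.nominal_offsets[i]).astype(int)
        off, score, lc = estimate_offset_pair(
            layout.tiles[i], layout.tiles[j], nominal, search_radius)
        pairwise[(i, j)] = (off, score)
        if lc:
            low_conf.append((i, j))
    sol = globalize_offsets(pairwise, layout)
    sol.low_confidence = low_conf
    return sol


def fuse(layout: TileLayout, solution: OffsetSolution,
         blend: str = "linear", return_weights: bool = False):
    """Fuse tiles at their solved positions with feathered overlaps.

    Per-tile weights ramp linearly from the tile border inward (saturating
    at `overlap_vox`), are normalized to sum to 1 wherever any tile
    contributes, and reduce to a copy where a single tile covers a voxel.
    """
    if blend not in ("linear", "nearest"):
        raise ValueError("blend must be 'linear' or 'nearest'")
    positions = np.round(solution.global_positions).astype(int)
    positions = positions - positions.min(axis=0)
    shapes = np.asarray([_as_array(t).shape for t in layout.tiles])
    out_shape = tuple((positions + shapes).max(axis=0))
    acc = np.zeros(out_shape)
    wacc = np.zeros(out_shape)
    for tile, pos in zip(layout.tiles, positions):
        arr = _as_array(tile)
        if blend == "linear":
            w = _feather_weights(arr.shape, layout.overlap_vox)
        else:
            w = np.ones(arr.shape)
        sl = tuple(slice(p, p + s) for p, s in zip(pos, arr.shape))
        acc[sl] += arr * w
        wacc[sl] += w
    covered = wacc > 0
    fused = np.zeros(out_shape)
    fused[covered] = acc[covered] / wacc[covered]
    voxel = (layout.tiles[0].voxel_m
             if isinstance(layout.tiles[0], ReconVolume) else 1.0)
    vol = ReconVolume(fused, voxel, provenance={
        "method": "fuse", "n_tiles": layout.n_tiles,
        "residual": solution.residual})
    if return_weights:
        return vol, wacc
    return vol


def _feather_weights(shape, overlap: int) -> np.ndarray:
    ramps = []
    for s in shape:
        r = np.minimum(np.arange(s) + 1, np.arange(s)[::-1] + 1)
        ramps.append(np.minimum(r / float(max(overlap, 1)), 1.0))
    return (ramps[0][:, None, None] * ramps[1][None, :, None]
            * ramps[2][None, None, :])


def make_overview(fused: ReconVolume, k: int = 4) -> ReconVolume:
    """k-fold binned low-resolution reference volume (default 4)."""
    return bin_volume(fused, k)
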