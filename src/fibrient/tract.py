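"""Visualization primitives: orientation glyphs and bidirectional streamlines.

Glyphs are a regular-grid subsample of the orientation field (every Nth
voxel, with the stride increased minimally to respect a vertex cap), each
colored by the out-of-plane angle.  Streamlines integrate the axial field
from randomly seeded voxels in both directions with a fixed-step midpoint
scheme; at every step the locally interpolated axial vectors are sign-
aligned with the running direction (axial fields have no global sign), and a
line stops when it leaves the boundary mask, enters an invalid voxel, turns
more than 60 degrees in one step, or reaches the point cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .orientation import OrientationField

__all__ = [
    "GlyphSet",
    "StreamlineSet",
    "PARULA",
    "parula_colors",
    "sample_glyphs",
    "trace_streamlines",
]

#: compact parula-like perceptual colormap (anchor RGB rows, interpolated)
PARULA = np.array([
    [0.2081, 0.1663, 0.5292],
    [0.1986, 0.3709, 0.8000],
    [0.1175, 0.5369, 0.8594],
    [0.0784, 0.6460, 0.8410],
    [0.0689, 0.7445, 0.7382],
    [0.2906, 0.8103, 0.5816],
    [0.6125, 0.8311, 0.3711],
    [0.8848, 0.8095, 0.2456],
    [0.9763, 0.9831, 0.0538],
])


def parula_colors(x: np.ndarray) -> np.ndarray:
    """Map values in [0, 1] to RGB via the parula-like lookup table."""
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    pos = x * (len(PARULA) - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, len(PARULA) - 1)
    t = (pos - lo)[..., None]
    return (1 - t) * PARULA[lo] + t * PARULA[hi]


@dataclass
class GlyphSet:
    """Sub-sampled oriented-cylinder primitives."""

    positions_um: np.ndarray  # (n, 3) xyz
    directions: np.ndarray  # (n, 3) axial unit vectors
    color_deg: np.ndarray  # arccos(|v_z|) in degrees (proportional to phi)
    stride_used: int
    length_um: float = 12.0
    radius_um: float = 1.5


@dataclass
class StreamlineSet:
    """Bidirectional mask-bounded polylines."""

    polylines: list  # list of (k, 3) float arrays, xyz in µm
    seed_indices: np.ndarray  # (n, 3) voxel coords (z, y, x) of the seeds
    color_deg: np.ndarray  # phi angle at the seed, degrees
    step_um: float = 2.0


def sample_glyphs(
    fieldv: OrientationField,
    stride: int = 12,
    max_vertices: int = 75000,
    voxel_size_um: float | None = None,
) -> GlyphSet:
    """Display every ``stride``-th voxel as a glyph, capped at ``max_vertices``.

    If the requested stride yields more glyphs than the cap, the stride is
    increased minimally until the cap is met.  The color scalar is the arc
    cosine of the absolute z-component of the orientation (in degrees),
    proportional to the out-of-plane angle phi.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    v = voxel_size_um if voxel_size_um is not None else fieldv.voxel_size_um
    s = int(stride)
    while True:
        sub_valid = fieldv.valid[::s, ::s, ::s]
        count = int(sub_valid.sum())
        if count <= max_vertices:
            break
        s += 1
    idx = np.argwhere(sub_valid) * s  # (n, 3) (z, y, x)
    if idx.size == 0:
        return GlyphSet(
            positions_um=np.zeros((0, 3)),
            directions=np.zeros((0, 3)),
            color_deg=np.zeros(0),
            stride_used=s,
        )
    vecs = fieldv.vectors[idx[:, 0], idx[:, 1], idx[:, 2]]
    pos = idx[:, ::-1].astype(float) * v  # -> xyz µm
    color = np.degrees(np.arccos(np.clip(np.abs(vecs[:, 2]), 0.0, 1.0)))
    return GlyphSet(positions_um=pos, directions=vecs, color_deg=color, stride_used=s)


def _gather_aligned(field_vectors, pos_vox, ref_dir, nearest=False):
    """Trilinear (or nearest) interpolation of axial vectors, sign-aligned
    to ``ref_dir`` corner-by-corner before weighting.

    ``pos_vox`` is (n, 3) in (z, y, x) voxel coordinates.
    """
    shape = np.asarray(field_vectors.shape[:3])
    if nearest:
        idx = np.clip(np.round(pos_vox).astype(int), 0, shape - 1)
        v = field_vectors[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.float64)
        sgn = np.where(np.sum(v * ref_dir, axis=-1) < 0, -1.0, 1.0)
        return v * sgn[:, None]
    base = np.floor(pos_vox).astype(int)
    frac = pos_vox - base
    out = np.zeros((pos_vox.shape[0], 3))
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                corner = base + np.array([dz, dy, dx])
                corner = np.clip(corner, 0, shape - 1)
                v = field_vectors[corner[:, 0], corner[:, 1], corner[:, 2]].astype(np.float64)
                sgn = np.where(np.sum(v * ref_dir, axis=-1) < 0, -1.0, 1.0)
                w = (
                    (frac[:, 0] if dz else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dx else 1 - frac[:, 2])
                )
                out += (v * sgn[:, None]) * w[:, None]
    return out


def _integrate(fieldv, inside, start_vox, start_dir, step_vox, max_points, nearest,
               max_turn_deg=60.0):
    """March all seeds simultaneously; returns per-seed point lists (voxel zyx)."""
    n = start_vox.shape[0]
    pts = [[p.copy()] for p in start_vox]
    pos = start_vox.astype(np.float64).copy()
    dirs = start_dir.astype(np.float64).copy()  # (n, 3) xyz
    active = np.ones(n, dtype=bool)
    cos_max = np.cos(np.deg2rad(max_turn_deg))
    shape = np.asarray(fieldv.vectors.shape[:3])

    for _ in range(max_points - 1):
        if not active.any():
            break
        ai = np.nonzero(active)[0]
        p = pos[ai]
        d = dirs[ai]
        # midpoint (RK2) step on the sign-aligned field; steps in voxel
        # coords use (z, y, x) = reversed xyz direction components
        k1 = _gather_aligned(fieldv.vectors, p, d, nearest)
        nk1 = np.linalg.norm(k1, axis=-1, keepdims=True)
        okv = nk1[:, 0] > 1e-9
        k1 = np.where(nk1 > 1e-9, k1 / np.where(nk1 > 1e-9, nk1, 1), 0.0)
        pm = p + 0.5 * step_vox * k1[:, ::-1]
        in_mid = np.all((pm >= 0) & (pm <= shape - 1), axis=1)
        k2 = np.zeros_like(k1)
        k2[in_mid] = _gather_aligned(fieldv.vectors, pm[in_mid], k1[in_mid], nearest)
        nk2 = np.linalg.norm(k2, axis=-1, keepdims=True)
        okv &= in_mid & (nk2[:, 0] > 1e-9)
        k2 = np.where(nk2 > 1e-9, k2 / np.where(nk2 > 1e-9, nk2, 1), 0.0)

        turn_ok = np.sum(k2 * d, axis=-1) >= cos_max
        newp = p + step_vox * k2[:, ::-1]
        in_bounds = np.all((newp >= 0) & (newp <= shape - 1), axis=1)
        nearest_idx = np.clip(np.round(newp).astype(int), 0, shape - 1)
        in_mask = inside[nearest_idx[:, 0], nearest_idx[:, 1], nearest_idx[:, 2]]
        keep = okv & turn_ok & in_bounds & in_mask

        for loc, gi in enumerate(ai):
            if keep[loc]:
                pts[gi].append(newp[loc])
                pos[gi] = newp[loc]
                dirs[gi] = k2[loc]
            else:
                active[gi] = False
    return pts


def trace_streamlines(
    fieldv: OrientationField,
    mask: np.ndarray,
    n_seeds: int = 25000,
    step_um: float = 2.0,
    max_points: int = 500,
    seed: int = 0,
    nearest: bool = False,
) -> StreamlineSet:
    """Bidirectional streamlines from randomly sampled valid voxels.

    Up to 25,000 seeds are drawn uniformly (seeded RNG) from voxels that are
    both valid in the field and inside the mask.  Each seed grows a forward
    and a backward line (the field is axial, so both senses are physical);
    the two are merged into one polyline.  No emitted point lies outside the
    mask.  Identical seeds give byte-identical output.
    """
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    n_seeds = int(min(n_seeds, 25000))
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fieldv.valid.shape:
        raise ValueError("mask and field must share a grid")
    inside = mask & fieldv.valid
    cand = np.argwhere(inside)
    if cand.shape[0] == 0:
        raise ValueError("no valid seed voxels")
    rng = np.random.default_rng(seed)
    take = min(n_seeds, cand.shape[0])
    sel = rng.choice(cand.shape[0], size=take, replace=False)
    seeds = cand[np.sort(sel)]

    v = fieldv.voxel_size_um
    step_vox = step_um / v
    d0 = fieldv.vectors[seeds[:, 0], seeds[:, 1], seeds[:, 2]].astype(np.float64)

    half = max(1, max_points // 2)
    fwd = _integrate(fieldv, inside, seeds.astype(float), d0, step_vox, half, nearest)
    bwd = _integrate(fieldv, inside, seeds.astype(float), -d0, step_vox, half, nearest)

    polylines = []
    for f, b in zip(fwd, bwd):
        arr = np.array(b[::-1] + f[1:], dtype=np.float64)
        polylines.append(arr[:, ::-1] * v)  # (z,y,x) voxels -> (x,y,z) µm
    color = np.degrees(np.arcsin(np.clip(np.abs(d0[:, 2]), 0.0, 1.0)))
    return StreamlineSet(
        polylines=polylines, seed_indices=seeds, color_deg=color, step_um=step_um
    )
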