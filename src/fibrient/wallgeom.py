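"""Cardiac coordinate frame and helix-angle analysis.

From a binary wall mask we derive, per voxel, the orthonormal triad
{C (circumferential), L (longitudinal), R (radial penetration, pointing from
the outer wall inward)} and the transmural depth from the outer boundary.
Cell orientations are then summarized by three angles:

* theta -- acute angle between the orientation's short-axis (XY) projection
  and the X axis, in [0, 90] degrees;
* phi   -- acute elevation out of the short-axis plane, in [0, 90] degrees;
* alpha_H (helix angle) -- signed angle between the orientation's projection
  onto the wall tangent plane {C, L} and the circumferential direction, in
  [-90, 90] degrees under axial equivalence.  Positive alpha_H tilts toward
  +L when moving along +C (right-handed convention).

Wedge-shaped sectors about the wall centroid yield transmural profiles of
the 3D-average helix angle versus depth; local slopes and continuous
piecewise-linear fits quantify the sharp outer-wall band the micron-scale
analysis resolves.

Averaging helix angles is done axially (via doubled-angle circular means),
never arithmetically: arithmetic means are wrong near the +/-90 wrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .orientation import OrientationField

__all__ = [
    "WallFrame",
    "AngleMaps",
    "SectorSpec",
    "TransmuralProfile",
    "estimate_centroid",
    "build_wall_frame",
    "compute_theta_phi",
    "compute_helix_angle",
    "axial_mean_deg",
    "sector_profile",
    "profile_rate_of_change",
    "piecewise_linear_fit",
]


@dataclass
class WallFrame:
    """Per-voxel orthonormal triad and transmural depth for a wall mask."""

    centroid_vox: np.ndarray  # (z, y, x) voxel coordinates of the mask centroid
    circumferential: np.ndarray  # (..., 3) xyz
    longitudinal: np.ndarray
    penetration: np.ndarray  # R, pointing from outer wall inward
    depth_um: np.ndarray
    valid: np.ndarray
    voxel_size_um: float = 2.0


@dataclass
class AngleMaps:
    """Per-voxel angle maps in degrees with validity flags."""

    theta_deg: np.ndarray | None = None
    phi_deg: np.ndarray | None = None
    alpha_h_deg: np.ndarray | None = None
    valid: np.ndarray | None = None
    theta_valid: np.ndarray | None = None


@dataclass
class SectorSpec:
    """Wedge sectors about the centroid in the short-axis plane."""

    reference_angle_deg: float = 0.0  # direction of the first wedge edge (lateral)
    wedge_width_deg: float = 10.0
    wedges_combined: int = 2
    depth_bin_um: float = 2.0

    def __post_init__(self):
        if self.wedge_width_deg <= 0 or self.depth_bin_um <= 0:
            raise ValueError("wedge width and depth bin must be positive")
        n = 360.0 / self.wedge_width_deg
        if abs(n - round(n)) > 1e-9:
            raise ValueError("wedge width must divide 360 degrees")
        if int(round(n)) % self.wedges_combined != 0:
            raise ValueError("wedges_combined must divide the number of wedges")


@dataclass
class TransmuralProfile:
    """Mean helix angle versus transmural depth for one combined sector."""

    sector_id: int
    depth_um: np.ndarray
    mean_alpha_deg: np.ndarray
    n_voxels: np.ndarray
    angle_range_deg: tuple = (0.0, 360.0)


def estimate_centroid(mask: np.ndarray, voxel_size_um: float = 2.0):
    """Foreground center of mass in voxel and physical (µm) coordinates."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    c = np.asarray(ndi.center_of_mass(m), dtype=float)  # (z, y, x)
    return c, c * voxel_size_um


def build_wall_frame(
    wall_mask: np.ndarray,
    centroid: np.ndarray | None = None,
    voxel_size_um: float = 2.0,
    long_axis=(0.0, 0.0, 1.0),
    normal_smooth_vox: float = 10.0,
) -> WallFrame:
    """Derive {C, L, R} and transmural depth from the outer wall boundary.

    The outer boundary is the mask surface facing the volume border (the
    background component connected to the border).  Transmural depth is the
    Euclidean distance to that boundary; the penetration direction R is the
    gradient of the (Gaussian-smoothed, scale ``normal_smooth_vox``) depth
    field, i.e. the smoothed inward boundary normal.  L is the global
    longitudinal axis orthogonalized against R, and C = L x R.
    """
    mask = np.asarray(wall_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty wall mask")
    if centroid is None:
        centroid, _ = estimate_centroid(mask, voxel_size_um)

    # background connected to the *lateral* volume border = outside the outer
    # boundary; the z faces are section cuts, not wall surfaces, so an
    # enclosed lumen touching them stays "inside"
    bg_labels, _ = ndi.label(~mask)
    border = np.zeros(mask.shape, dtype=bool)
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    outer_ids = np.setdiff1d(np.unique(bg_labels[border & ~mask]), [0])
    outer_bg = np.isin(bg_labels, outer_ids)

    depth_vox = ndi.distance_transform_edt(~outer_bg)
    depth_um = np.clip((depth_vox - 0.5), 0.0, None) * voxel_size_um

    sm = ndi.gaussian_filter(depth_vox, normal_smooth_vox, mode="nearest")
    gz, gy, gx = np.gradient(sm)
    R = np.stack([gx, gy, gz], axis=-1)
    nrm = np.linalg.norm(R, axis=-1, keepdims=True)
    ok = (nrm[..., 0] > 1e-9) & mask
    R = np.where(nrm > 1e-9, R / np.where(nrm > 1e-9, nrm, 1.0), 0.0)

    L0 = np.asarray(long_axis, dtype=float)
    L0 = L0 / np.linalg.norm(L0)
    proj = (R @ L0)[..., None]
    L = L0 - proj * R
    lnrm = np.linalg.norm(L, axis=-1, keepdims=True)
    ok &= lnrm[..., 0] > 1e-6
    L = np.where(lnrm > 1e-6, L / np.where(lnrm > 1e-6, lnrm, 1.0), 0.0)
    C = np.cross(L, R)

    # per-slice sanity: in an annulus-like mask every slice should enclose
    # a lumen behind a closed ring; a slice whose ring is broken (its
    # in-plane background all drains to the border) is flagged invalid
    slice_has_mask = [bool(mask[z].any()) for z in range(mask.shape[0])]
    slice_closed = []
    for z in range(mask.shape[0]):
        if not slice_has_mask[z]:
            slice_closed.append(None)
            continue
        bg2, _ = ndi.label(~mask[z])
        border2 = np.zeros_like(mask[z])
        border2[0, :] = border2[-1, :] = border2[:, 0] = border2[:, -1] = True
        out2 = np.setdiff1d(np.unique(bg2[border2 & ~mask[z]]), [0])
        lumen = ~mask[z] & ~np.isin(bg2, out2)
        slice_closed.append(bool(lumen.any()))
    if any(c is True for c in slice_closed):
        for z, closed in enumerate(slice_closed):
            if closed is False:
                warnings.warn(
                    f"slice {z}: outer boundary not closed; voxels flagged invalid"
                )
                ok[z] = False

    return WallFrame(
        centroid_vox=np.asarray(centroid, dtype=float),
        circumferential=C.astype(np.float32),
        longitudinal=L.astype(np.float32),
        penetration=R.astype(np.float32),
        depth_um=depth_um.astype(np.float32),
        valid=ok,
        voxel_size_um=voxel_size_um,
    )


def compute_theta_phi(fieldv: OrientationField) -> AngleMaps:
    """In-plane angle to X (theta) and out-of-plane elevation (phi).

    For a unit vector v = (vx, vy, vz): phi = arcsin(|vz|) and
    theta = arccos(|vx| / ||(vx, vy)||), both reported as magnitudes in
    [0, 90] degrees.  theta is undefined (flagged) for near-vertical vectors
    whose XY projection vanishes.
    """
    v = fieldv.vectors
    vx, vy, vz = v[..., 0], v[..., 1], v[..., 2]
    phi = np.degrees(np.arcsin(np.clip(np.abs(vz), 0.0, 1.0)))
    pxy = np.hypot(vx, vy)
    theta_ok = fieldv.valid & (pxy >= 1e-6)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.degrees(np.arccos(np.clip(np.abs(vx) / np.where(pxy > 0, pxy, 1.0), 0.0, 1.0)))
    theta = np.where(theta_ok, theta, np.nan)
    phi = np.where(fieldv.valid, phi, np.nan)
    return AngleMaps(
        theta_deg=theta.astype(np.float32),
        phi_deg=phi.astype(np.float32),
        valid=fieldv.valid.copy(),
        theta_valid=theta_ok,
    )


def _wrap_axial_deg(a: np.ndarray) -> np.ndarray:
    """Map angles to (-90, 90] under axial (180-degree) equivalence."""
    return -((-np.asarray(a) + 90.0) % 180.0 - 90.0)


def compute_helix_angle(fieldv: OrientationField, frame: WallFrame) -> AngleMaps:
    """Signed angle from C of the orientation's tangent-plane projection.

    alpha_H = atan2(<v, L>, <v, C>) mapped into (-90, 90] axially.  Voxels
    whose tangent-plane projection nearly vanishes (orientation along R), or
    where field/frame are invalid, are flagged.
    """
    if fieldv.vectors.shape[:-1] != frame.depth_um.shape:
        raise ValueError("orientation field and wall frame must share a grid")
    v = fieldv.vectors.astype(np.float64)
    vc = np.sum(v * frame.circumferential, axis=-1)
    vl = np.sum(v * frame.longitudinal, axis=-1)
    proj = np.hypot(vc, vl)
    ok = fieldv.valid & frame.valid & (proj >= 1e-6)
    alpha = _wrap_axial_deg(np.degrees(np.arctan2(vl, vc)))
    alpha = np.where(ok, alpha, np.nan)
    return AngleMaps(alpha_h_deg=alpha.astype(np.float32), valid=ok)


def axial_mean_deg(angles_deg: np.ndarray) -> float:
    """Axial (orientation) mean of angles in degrees, result in (-90, 90].

    Equivalent to the principal-eigenvector angle of the mean outer product
    of tangent-plane unit vectors: the circular mean of doubled angles.
    """
    a2 = np.deg2rad(np.asarray(angles_deg, dtype=float) * 2.0)
    s, c = np.sin(a2).sum(), np.cos(a2).sum()
    return float(_wrap_axial_deg(np.degrees(0.5 * np.arctan2(s, c))))


def sector_profile(
    alpha: AngleMaps,
    frame: WallFrame,
    spec: SectorSpec | None = None,
    mask: np.ndarray | None = None,
) -> list:
    """Transmural helix-angle profiles for combined wedge sectors.

    Voxels are assigned to wedges by their angular position about the mask
    centroid in the short-axis (XY) plane; wedges are grouped
    ``wedges_combined`` at a time, and within each (sector, depth bin) the
    helix angles of all slices are averaged axially (the "3D average").
    Empty bins are omitted.
    """
    spec = spec or SectorSpec()
    ok = alpha.valid & frame.valid
    if mask is not None:
        ok = ok & np.asarray(mask, dtype=bool)
    if not ok.any():
        raise ValueError("no valid voxels to profile")

    shape = ok.shape
    cz, cy, cx = frame.centroid_vox
    yy, xx = np.meshgrid(np.arange(shape[1]) - cy, np.arange(shape[2]) - cx, indexing="ij")
    psi = (np.degrees(np.arctan2(yy, xx)) - spec.reference_angle_deg) % 360.0
    wedge2d = np.floor(psi / spec.wedge_width_deg).astype(int)
    n_wedges = int(round(360.0 / spec.wedge_width_deg))
    wedge2d = np.clip(wedge2d, 0, n_wedges - 1)
    group2d = wedge2d // spec.wedges_combined
    n_groups = n_wedges // spec.wedges_combined
    group = np.broadcast_to(group2d, shape)

    depth_bin = np.floor(frame.depth_um / spec.depth_bin_um).astype(int)
    n_bins = int(depth_bin[ok].max()) + 1

    g = group[ok]
    b = depth_bin[ok]
    a2 = np.deg2rad(alpha.alpha_h_deg[ok].astype(np.float64) * 2.0)
    flat = g * n_bins + b
    size = n_groups * n_bins
    cnt = np.bincount(flat, minlength=size)
    ssum = np.bincount(flat, weights=np.sin(a2), minlength=size)
    csum = np.bincount(flat, weights=np.cos(a2), minlength=size)
    mean = _wrap_axial_deg(np.degrees(0.5 * np.arctan2(ssum, csum)))

    profiles = []
    span = spec.wedge_width_deg * spec.wedges_combined
    for gi in range(n_groups):
        row = slice(gi * n_bins, (gi + 1) * n_bins)
        c = cnt[row]
        keep = c > 0
        bins = np.nonzero(keep)[0]
        if bins.size == 0:
            continue
        profiles.append(
            TransmuralProfile(
                sector_id=gi,
                depth_um=(bins + 0.5) * spec.depth_bin_um,
                mean_alpha_deg=mean[row][keep],
                n_voxels=c[keep],
                angle_range_deg=(
                    spec.reference_angle_deg + gi * span,
                    spec.reference_angle_deg + (gi + 1) * span,
                ),
            )
        )
    return profiles


def profile_rate_of_change(profile: TransmuralProfile, window_voxels: int = 15):
    """Local slope (degrees per µm) by sliding least-squares line fits.

    The window spans ``window_voxels`` profile samples (15 samples at 2 µm
    bins = a 30 µm neighborhood).  Returns ``(depth_centers_um, slopes)``
    for windows that fit entirely inside the profile.
    """
    x = np.asarray(profile.depth_um, dtype=float)
    y = np.asarray(profile.mean_alpha_deg, dtype=float)
    w = int(window_voxels)
    if x.size <= w:
        raise ValueError("profile shorter than the slope window")
    n = x.size - w + 1
    centers = np.empty(n)
    slopes = np.empty(n)
    for i in range(n):
        xs, ys = x[i:i + w], y[i:i + w]
        xm, ym = xs.mean(), ys.mean()
        slopes[i] = np.sum((xs - xm) * (ys - ym)) / np.sum((xs - xm) ** 2)
        centers[i] = xm
    return centers, slopes


def piecewise_linear_fit(profile: TransmuralProfile, n_segments: int = 2) -> dict:
    """Continuous piecewise-linear least squares with free breakpoints.

    Breakpoints are grid-searched over the profile samples (earliest wins on
    ties) with closed-form hinge-basis fits per candidate.  The first
    segment's length estimates the outer-band extent.  Returns a dict with
    ``breakpoints_um``, ``slopes_deg_per_um``, ``segment_lengths_um``,
    ``sse`` and a ``degenerate`` flag raised when an extra segment buys
    nothing (all slopes equal).
    """
    x = np.asarray(profile.depth_um, dtype=float)
    y = np.asarray(profile.mean_alpha_deg, dtype=float)
    k = int(n_segments)
    if k < 1:
        raise ValueError("need at least one segment")
    if x.size < 2 * k:
        raise ValueError("profile too short for the requested segments")

    def fit(breaks):
        cols = [np.ones_like(x), x] + [np.clip(x - b, 0.0, None) for b in breaks]
        A = np.stack(cols, axis=1)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        return float(resid @ resid), coef

    if k == 1:
        best_breaks: tuple = ()
        best_sse, best_coef = fit(())
    else:
        # candidate breakpoints at interior sample positions
        cand = x[1:-1]
        best_sse, best_coef, best_breaks = np.inf, None, ()
        from itertools import combinations

        for breaks in combinations(cand, k - 1):
            sse, coef = fit(breaks)
            if sse < best_sse - 1e-12:
                best_sse, best_coef, best_breaks = sse, coef, breaks

    slopes = np.cumsum(best_coef[1:])  # hinge coefficients accumulate
    edges = np.concatenate([[x[0]], np.asarray(best_breaks, dtype=float), [x[-1]]])
    lengths = np.diff(edges)
    degenerate = bool(k > 1 and np.allclose(slopes, slopes[0], atol=1e-6))
    return {
        "breakpoints_um": list(best_breaks),
        "slopes_deg_per_um": slopes.tolist(),
        "segment_lengths_um": lengths.tolist(),
        "sse": best_sse,
        "degenerate": degenerate,
    }
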