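"""Per-voxel cell-orientation estimation from image gradients.

The local orientation of an elongated cell is the direction in which the
image intensity varies least.  At each voxel we form the structure tensor

    J(x) = G_w * (grad I grad I^T),

where the gradient is computed by Gaussian-derivative filtering at scale
``sigma_gradient`` and the outer products are averaged with a Gaussian window
at scale ``sigma_window``.  The estimated cell long axis is the eigenvector
of J belonging to the eigenvalue of smallest magnitude; fractional anisotropy
of the eigenvalues grades how trustworthy the estimate is.  Element-wise
block averaging of the tensors emulates coarse (DT-MRI-like) voxel sizes.

Vectors are axial (v and -v are the same orientation); all consumers must
respect that.  Component order is (x, y, z); arrays are indexed (z, y, x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "StructureTensorField",
    "OrientationField",
    "compute_structure_tensor",
    "smallest_eigenvector_field",
    "fractional_anisotropy",
    "coarsen_tensor_field",
    "repeat_blocks",
    "angular_error",
    "cell_axis_from_mask",
    "canonical_sign",
]

#: components of the symmetric tensor in upper-triangle (xyz) order
TENSOR_CHANNELS = ("xx", "xy", "xz", "yy", "yz", "zz")


@dataclass
class StructureTensorField:
    """Per-voxel symmetric 3x3 PSD tensor, stored as (nz, ny, nx, 3, 3)."""

    tensor: np.ndarray
    sigma_gradient_um: float
    sigma_window_um: float
    voxel_size_um: float

    @property
    def shape(self):
        return self.tensor.shape[:3]


@dataclass
class OrientationField:
    """Per-voxel axial unit vectors (xyz order) with a validity mask.

    ``canonical_sign`` records that each vector's first nonzero component has
    been made positive; the semantics remain axial regardless.
    """

    vectors: np.ndarray
    valid: np.ndarray
    voxel_size_um: float = 2.0
    canonical: bool = True


def compute_structure_tensor(
    vol: np.ndarray,
    sigma_gradient_um: float = 2.0,
    sigma_window_um: float = 8.0,
    voxel_size_um: float = 2.0,
) -> StructureTensorField:
    """Gaussian-derivative gradients, windowed outer products."""
    vol = np.asarray(vol, dtype=np.float64)
    if vol.ndim != 3 or min(vol.shape) < 5:
        raise ValueError("volume must be 3D with at least 5 voxels per axis")
    if sigma_gradient_um <= 0 or sigma_window_um <= 0:
        raise ValueError("smoothing scales must be positive")
    if min(sigma_gradient_um, sigma_window_um) < voxel_size_um / 2:
        warnings.warn("smoothing scale below half a voxel: aliasing risk")

    sg = sigma_gradient_um / voxel_size_um
    sw = sigma_window_um / voxel_size_um
    # gradients along array axes (z, y, x), reordered to (x, y, z)
    gz = ndi.gaussian_filter(vol, sg, order=(1, 0, 0), mode="reflect")
    gy = ndi.gaussian_filter(vol, sg, order=(0, 1, 0), mode="reflect")
    gx = ndi.gaussian_filter(vol, sg, order=(0, 0, 1), mode="reflect")
    g = (gx, gy, gz)

    J = np.empty(vol.shape + (3, 3), dtype=np.float32)
    for i in range(3):
        for j in range(i, 3):
            Jij = ndi.gaussian_filter(g[i] * g[j], sw, mode="reflect")
            J[..., i, j] = Jij
            if i != j:
                J[..., j, i] = Jij
    return StructureTensorField(J, sigma_gradient_um, sigma_window_um, voxel_size_um)


def _eigh_field(tensor: np.ndarray):
    w, V = np.linalg.eigh(tensor.astype(np.float64))
    return w, V


def canonical_sign(vectors: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Flip axial vectors so the first nonzero component is positive."""
    v = np.asarray(vectors, dtype=np.float64)
    sx = np.where(np.abs(v[..., 0]) > eps, np.sign(v[..., 0]), 0.0)
    sy = np.where(np.abs(v[..., 1]) > eps, np.sign(v[..., 1]), 0.0)
    sz = np.where(np.abs(v[..., 2]) > eps, np.sign(v[..., 2]), 0.0)
    s = np.where(sx != 0, sx, np.where(sy != 0, sy, np.where(sz != 0, sz, 1.0)))
    return v * s[..., None]


def smallest_eigenvector_field(
    tf: StructureTensorField,
    fa_floor: float = 0.1,
    degeneracy_floor: float = 0.05,
    mask: np.ndarray | None = None,
) -> OrientationField:
    """Orientation = eigenvector of the smallest-magnitude eigenvalue.

    Voxels where the tensor is (near-)isotropic carry no orientation signal:
    those with FA below ``fa_floor``, or whose two smallest eigenvalues are
    within ``degeneracy_floor`` of each other relative to the largest, are
    flagged invalid instead of raising.  Pass ``fa_floor=0`` and
    ``degeneracy_floor=0`` to keep every voxel with a nonzero tensor (the
    coarse-resolution analysis mode).  An optional ``mask`` restricts the
    (eigen-decomposition) work to a region of interest.
    """
    shape = tf.shape
    out_dtype = np.float64 if tf.tensor.dtype == np.float64 else np.float32
    vectors = np.zeros(shape + (3,), dtype=out_dtype)
    valid = np.zeros(shape, dtype=bool)

    if mask is None:
        tensors = tf.tensor.reshape(-1, 3, 3)
        sel = None
    else:
        sel = np.asarray(mask, dtype=bool)
        tensors = tf.tensor[sel]
    if tensors.size == 0:
        return OrientationField(vectors, valid, tf.voxel_size_um)

    w, V = _eigh_field(tensors)
    order = np.argsort(np.abs(w), axis=-1)  # by |lambda|, per the method
    idx_min = order[..., 0]
    n = w.shape[0]
    v_min = V[np.arange(n), :, idx_min]

    w_sorted = np.sort(w, axis=-1)
    w_max = w_sorted[..., 2]
    gap = np.where(w_max > 0, (w_sorted[..., 1] - w_sorted[..., 0]) / np.where(w_max > 0, w_max, 1.0), 0.0)
    fa = _fa_from_eigvals(w)
    ok = (w_max > 0) & (fa >= fa_floor) & (gap >= degeneracy_floor)

    v_min = canonical_sign(v_min)
    nrm = np.linalg.norm(v_min, axis=-1, keepdims=True)
    v_min = np.where(nrm > 0, v_min / np.where(nrm > 0, nrm, 1.0), 0.0)

    if sel is None:
        vectors = v_min.reshape(shape + (3,)).astype(out_dtype)
        valid = ok.reshape(shape)
        vectors[~valid] = 0.0
    else:
        vectors[sel] = np.where(ok[:, None], v_min, 0.0).astype(out_dtype)
        valid[sel] = ok
    return OrientationField(vectors, valid, tf.voxel_size_um)


def _fa_from_eigvals(w: np.ndarray) -> np.ndarray:
    lam = np.clip(w, 0.0, None)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    fa = np.sqrt(1.5) * np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return np.clip(fa, 0.0, 1.0)


def fractional_anisotropy(tf: StructureTensorField) -> np.ndarray:
    """FA = sqrt(3/2) ||lambda - mean|| / ||lambda||, in [0, 1]; 0 for zero tensors."""
    w = np.linalg.eigvalsh(tf.tensor.astype(np.float64))
    out_dtype = np.float64 if tf.tensor.dtype == np.float64 else np.float32
    return _fa_from_eigvals(w).astype(out_dtype)


def _block_reduce_mean(arr: np.ndarray, block: tuple) -> np.ndarray:
    """Exact block means along the three leading axes (ragged edges allowed)."""
    out = arr.astype(np.float64)
    for ax, b in enumerate(block):
        n = out.shape[ax]
        starts = np.arange(0, n, b)
        sums = np.add.reduceat(out, starts, axis=ax)
        counts = np.diff(np.append(starts, n)).astype(np.float64)
        cshape = [1] * out.ndim
        cshape[ax] = len(starts)
        out = sums / counts.reshape(cshape)
    return out


def coarsen_tensor_field(tf: StructureTensorField, block) -> StructureTensorField:
    """Element-wise average of tensors over blocks (pseudo low-resolution).

    ``block`` is an integer factor (or per-axis triple) in voxels; a factor of
    250 at 2 µm voxels emulates a ~500 µm acquisition.  Factors larger than
    the field collapse that axis to a single tensor.
    """
    if np.isscalar(block):
        block = (int(block),) * 3
    block = tuple(max(1, min(int(b), s)) for b, s in zip(block, tf.shape))
    coarse = _block_reduce_mean(tf.tensor, block).astype(np.float32)
    return StructureTensorField(
        coarse, tf.sigma_gradient_um, tf.sigma_window_um, tf.voxel_size_um
    )


def repeat_blocks(arr: np.ndarray, block, shape) -> np.ndarray:
    """Upsample a block-reduced array back onto the fine grid by repetition."""
    if np.isscalar(block):
        block = (int(block),) * 3
    out = arr
    for ax, b in enumerate(block):
        out = np.repeat(out, b, axis=ax)
    slices = tuple(slice(0, s) for s in shape)
    return out[slices]


def angular_error(
    est, truth, mask: np.ndarray | None = None
):
    """Per-voxel acute angle between two axial fields, with summary stats.

    Accepts :class:`OrientationField` or raw ``(..., 3)`` arrays.  Returns
    ``(mean_deg, sd_deg, per_voxel_map_deg)``; the map is NaN outside the
    evaluated voxels.
    """
    ve = est.vectors if isinstance(est, OrientationField) else np.asarray(est)
    vt = truth.vectors if isinstance(truth, OrientationField) else np.asarray(truth)
    if ve.shape != vt.shape:
        raise ValueError("fields must share a grid")
    m = np.ones(ve.shape[:-1], dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if isinstance(est, OrientationField):
        m = m & est.valid
    if isinstance(truth, OrientationField):
        m = m & truth.valid
    if not m.any():
        raise ValueError("empty evaluation mask")
    dot = np.abs(np.sum(ve * vt, axis=-1))
    nrm = np.linalg.norm(ve, axis=-1) * np.linalg.norm(vt, axis=-1)
    cosang = np.clip(np.divide(dot, nrm, out=np.zeros_like(dot), where=nrm > 0), 0.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    out = np.where(m, ang, np.nan)
    vals = ang[m]
    return float(vals.mean()), float(vals.std()), out


def cell_axis_from_mask(cell_mask: np.ndarray):
    """Long axis of a segmented cell from the second-moment matrix.

    Returns ``(axis_xyz, degenerate)`` -- the principal eigenvector (largest
    eigenvalue) of the coordinate covariance of foreground voxels, and a flag
    raised for near-spherical masks whose principal axis is ill-defined.
    """
    coords = np.argwhere(np.asarray(cell_mask, dtype=bool))  # (n, 3) in (z, y, x)
    if coords.shape[0] == 0:
        raise ValueError("empty cell mask")
    if coords.shape[0] < 2:
        raise ValueError("single-voxel mask has no orientation")
    xyz = coords[:, ::-1].astype(np.float64)  # -> (x, y, z)
    xyz -= xyz.mean(axis=0)
    cov = xyz.T @ xyz / xyz.shape[0]
    w, V = np.linalg.eigh(cov)
    axis = canonical_sign(V[:, 2])
    degenerate = bool((w[2] - w[1]) / max(w[2], 1e-300) < 0.05)
    return axis / np.linalg.norm(axis), degenerate
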