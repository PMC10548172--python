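"""Shared fixtures and independent oracle helpers.

Heavy full-scale phantoms live in test_acceptance; the fixtures here are
compact versions for unit tests.  The oracle functions are deliberately
written without the library routines they check.
"""

import numpy as np
import pytest

import fibrient as fb


@pytest.fixture(scope="session")
def small_annulus():
    """Compact helical annulus with the default linear helix-angle ramp."""
    spec = fb.PhantomSpec(shape=(32, 120, 120))
    vol, gt = fb.make_helical_annulus(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def small_bundle():
    spec = fb.PhantomSpec(shape=(32, 64, 64), geometry="straight_bundle",
                          direction=(0.0, 0.0, 1.0))
    vol, gt = fb.make_straight_bundle(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def small_frame(small_annulus):
    _, _, gt = small_annulus
    return fb.build_wall_frame(gt.mask, voxel_size_um=2.0)


def axial_diff_deg(a, b):
    """Acute difference between two angle maps under 180-degree equivalence."""
    d = np.abs(np.asarray(a) - np.asarray(b))
    return np.minimum(d, 180.0 - d)


# ------------------------------------------------------ independent oracles

def brute_force_smallest_eigvec(A):
    """Smallest-|lambda| eigenvector via the characteristic polynomial.

    Roots from np.roots on det(A - lambda I); the eigenvector is the cross
    product of two rows of (A - lambda I).  Independent of np.linalg.eigh.
    """
    a = np.asarray(A, dtype=np.float64)
    c2 = -np.trace(a)
    c1 = (a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
          + a[0, 0] * a[2, 2] - a[0, 2] * a[2, 0]
          + a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1])
    c0 = -np.linalg.det(a)
    roots = np.roots([1.0, c2, c1, c0]).real
    # Newton-polish each root on the cubic for full double precision
    for _ in range(3):
        p = roots**3 + c2 * roots**2 + c1 * roots + c0
        dp = 3 * roots**2 + 2 * c2 * roots + c1
        roots = np.where(np.abs(dp) > 0, roots - p / dp, roots)
    lam = roots[np.argmin(np.abs(roots))]
    M = a - lam * np.eye(3)
    crosses = [np.cross(M[i], M[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
    v = max(crosses, key=np.linalg.norm)
    return v / np.linalg.norm(v)


def reflect_index(i, n):
    """scipy 'reflect' (half-sample symmetric) index folding."""
    period = 2 * n
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - 1 - i


def rl_tv_one_iteration_literal(img, psf, tv_weight, eps=1e-8):
    """Per-voxel transcription of the RL-TV update (nested loops only)."""
    nz, ny, nx = img.shape
    kz, ky, kx = psf.shape
    hz, hy, hx = kz // 2, ky // 2, kx // 2
    psf = psf / psf.sum()

    def conv(src, kernel):
        out = np.zeros_like(src)
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    acc = 0.0
                    for a in range(kz):
                        for b in range(ky):
                            for c in range(kx):
                                zz = reflect_index(z + a - hz, nz)
                                yy = reflect_index(y + b - hy, ny)
                                xx = reflect_index(x + c - hx, nx)
                                acc += kernel[kz - 1 - a, ky - 1 - b, kx - 1 - c] \
                                    * src[zz, yy, xx]
                    out[z, y, x] = acc
        return out

    o = img.astype(np.float64).copy()
    blur = conv(o, psf)
    ratio = img / np.maximum(blur, 1e-12)
    corr = conv(ratio, psf[::-1, ::-1, ::-1])
    if tv_weight == 0:
        return np.clip(o * corr, 0, None)
    axes = [ax for ax in range(3) if img.shape[ax] > 1]
    grads = {ax: np.gradient(o, axis=ax) for ax in axes}
    mag = np.sqrt(sum(g**2 for g in grads.values())) + eps
    div = sum(np.gradient(grads[ax] / mag, axis=ax) for ax in axes)
    denom = np.maximum(1.0 - tv_weight * div, 1e-12)
    return np.clip(o * corr / denom, 0, None)
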