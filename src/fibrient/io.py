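"""Readers and writers for every on-disk artifact, plus run configuration.

Conventions (also recorded in file headers where the format allows):
angles are degrees, coordinates are µm, volumes are multi-page TIFF indexed
(z, y, x), vector fields are 3-channel NRRD in xyz order, tensor fields are
6-channel NRRD in upper-triangle order (xx, xy, xz, yy, yz, zz), profiles
are CSV, fits/offsets/provenance are JSON, and tract output is legacy ASCII
VTK polydata.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import __version__ as _version
from .orientation import OrientationField, StructureTensorField, TENSOR_CHANNELS
from .tract import GlyphSet, StreamlineSet
from .wallgeom import TransmuralProfile

__all__ = [
    "read_stack",
    "write_stack",
    "read_vector_field",
    "write_vector_field",
    "read_tensor_field",
    "write_tensor_field",
    "write_nrrd",
    "read_nrrd",
    "profiles_to_csv",
    "read_profiles_csv",
    "write_vtk_polylines",
    "write_vtk_glyphs",
    "RunConfig",
    "Provenance",
]


# ---------------------------------------------------------------- TIFF stacks

def write_stack(vol: np.ndarray, path, voxel_size_um: float = 2.0) -> None:
    """Write a 3D volume as multi-page TIFF with voxel size in the metadata."""
    vol = np.asarray(vol)
    if vol.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) volume")
    tifffile.imwrite(
        path,
        vol,
        imagej=True,
        resolution=(1.0 / voxel_size_um, 1.0 / voxel_size_um),
        metadata={"spacing": voxel_size_um, "unit": "um", "axes": "ZYX"},
    )


def read_stack(path, voxel_size_um: float | None = None):
    """Read a multi-page TIFF; returns ``(volume, voxel_size_um)``.

    The voxel size comes from the TIFF resolution tags / ImageJ metadata;
    if absent, ``voxel_size_um`` is the fallback (with a warning).
    Single-channel grayscale only: RGB pages are an error.
    """
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"mixed page shapes {shapes} in {path}")
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(
                f"{path}: expected single-channel grayscale pages, got "
                f"{page.samplesperpixel} samples/pixel (is this an RGB TIFF?)"
            )
        vol = tf.asarray()
        found = None
        ij = tf.imagej_metadata or {}
        if "spacing" in ij:
            found = float(ij["spacing"])
        else:
            tags = page.tags
            if "XResolution" in tags:
                num, den = tags["XResolution"].value
                # (1, 1) is the writer's placeholder, not a real calibration
                if num > 0 and (num, den) != (1, 1):
                    found = den / num
    if vol.ndim == 2:
        vol = vol[None]
    if found is None:
        if voxel_size_um is None:
            voxel_size_um = 2.0
        warnings.warn(f"{path}: no resolution tags; using voxel size {voxel_size_um} µm")
        found = float(voxel_size_um)
    return vol, found


# ----------------------------------------------------------------------- NRRD

_NRRD_TYPES = {
    "float": np.float32,
    "double": np.float64,
    "unsigned char": np.uint8,
    "short": np.int16,
    "int": np.int32,
}


def write_nrrd(path, array: np.ndarray, spacings=None, keyvalues: dict | None = None) -> None:
    """Minimal single-file NRRD writer (raw little-endian encoding)."""
    arr = np.ascontiguousarray(array)
    typename = {np.dtype(v): k for k, v in _NRRD_TYPES.items()}.get(arr.dtype)
    if typename is None:
        arr = arr.astype(np.float32)
        typename = "float"
    lines = [
        "NRRD0004",
        "# fibrient field file; degrees and micrometre conventions",
        f"type: {typename}",
        f"dimension: {arr.ndim}",
        "sizes: " + " ".join(str(s) for s in arr.shape[::-1]),  # fastest axis first
        "endian: little",
        "encoding: raw",
    ]
    if spacings is not None:
        lines.append("spacings: " + " ".join(str(s) for s in spacings))
    for k, v in (keyvalues or {}).items():
        lines.append(f"{k}:={v}")
    header = "\n".join(lines) + "\n\n"
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(arr.astype(arr.dtype.newbyteorder("<")).tobytes())


def read_nrrd(path):
    """Read a single-file raw-encoded NRRD; returns ``(array, header_dict)``."""
    with open(path, "rb") as fh:
        raw = fh.read()
    end = raw.index(b"\n\n")
    header_lines = raw[:end].decode("ascii").splitlines()
    data = raw[end + 2:]
    hdr: dict = {}
    for line in header_lines[1:]:
        if line.startswith("#") or not line.strip():
            continue
        if ":=" in line:
            k, v = line.split(":=", 1)
            hdr[k.strip()] = v.strip()
        elif ":" in line:
            k, v = line.split(":", 1)
            hdr[k.strip()] = v.strip()
    sizes = [int(s) for s in hdr["sizes"].split()]
    dtype = _NRRD_TYPES[hdr["type"]]
    count = int(np.prod(sizes))
    arr = np.frombuffer(data, dtype=np.dtype(dtype).newbyteorder("<"), count=count)
    return arr.reshape(sizes[::-1]).copy(), hdr


def write_vector_field(path, fieldv: OrientationField) -> None:
    """Orientation field as 3-channel NRRD (xyz) plus a sibling validity TIFF."""
    path = Path(path)
    arr = np.moveaxis(fieldv.vectors.astype(np.float32), -1, 0)  # (3, z, y, x)
    v = fieldv.voxel_size_um
    write_nrrd(
        path,
        arr,
        spacings=["nan", v, v, v],
        keyvalues={
            "fibrient channel order": "vector xyz",
            "fibrient sign convention": "axial; first nonzero component positive",
            "fibrient voxel size um": v,
        },
    )
    write_stack(fieldv.valid.astype(np.uint8), path.with_name(path.stem + "_valid.tif"), v)


def read_vector_field(path) -> OrientationField:
    path = Path(path)
    arr, hdr = read_nrrd(path)
    if arr.shape[0] != 3:
        raise ValueError(f"{path}: expected 3 vector channels, found {arr.shape[0]}")
    v = float(hdr.get("fibrient voxel size um", 2.0))
    valid_path = path.with_name(path.stem + "_valid.tif")
    if valid_path.exists():
        valid, vv = read_stack(valid_path, v)
        if abs(vv - v) > 1e-6:
            raise ValueError(f"voxel spacing mismatch between {path} and {valid_path}")
        valid = valid.astype(bool)
    else:
        valid = np.ones(arr.shape[1:], dtype=bool)
    return OrientationField(np.moveaxis(arr, 0, -1), valid, v)


def write_tensor_field(path, tf: StructureTensorField) -> None:
    """Tensor field as 6-channel NRRD, upper-triangle order xx,xy,xz,yy,yz,zz."""
    J = tf.tensor
    chans = np.stack(
        [J[..., 0, 0], J[..., 0, 1], J[..., 0, 2], J[..., 1, 1], J[..., 1, 2], J[..., 2, 2]],
        axis=0,
    ).astype(np.float32)
    v = tf.voxel_size_um
    write_nrrd(
        path,
        chans,
        spacings=["nan", v, v, v],
        keyvalues={
            "fibrient channel order": " ".join(TENSOR_CHANNELS),
            "fibrient sigma gradient um": tf.sigma_gradient_um,
            "fibrient sigma window um": tf.sigma_window_um,
            "fibrient voxel size um": v,
        },
    )


def read_tensor_field(path) -> StructureTensorField:
    arr, hdr = read_nrrd(path)
    if arr.shape[0] != 6:
        raise ValueError(f"{path}: expected 6 tensor channels, found {arr.shape[0]}")
    shape = arr.shape[1:]
    J = np.empty(shape + (3, 3), dtype=np.float32)
    xx, xy, xz, yy, yz, zz = arr
    J[..., 0, 0], J[..., 0, 1], J[..., 0, 2] = xx, xy, xz
    J[..., 1, 0], J[..., 1, 1], J[..., 1, 2] = xy, yy, yz
    J[..., 2, 0], J[..., 2, 1], J[..., 2, 2] = xz, yz, zz
    return StructureTensorField(
        J,
        float(hdr.get("fibrient sigma gradient um", 2.0)),
        float(hdr.get("fibrient sigma window um", 8.0)),
        float(hdr.get("fibrient voxel size um", 2.0)),
    )


# ------------------------------------------------------------ profiles / fits

def profiles_to_csv(profiles: list, path) -> None:
    """Transmural profiles as CSV: sector, depth_um, mean_alpha_deg, n."""
    import pandas as pd

    rows = []
    for p in profiles:
        for d, a, n in zip(p.depth_um, p.mean_alpha_deg, p.n_voxels):
            rows.append({"sector": p.sector_id, "depth_um": d,
                         "mean_alpha_deg": a, "n": int(n)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles_csv(path) -> list:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for sid, g in df.groupby("sector"):
        g = g.sort_values("depth_um")
        out.append(TransmuralProfile(
            sector_id=int(sid),
            depth_um=g["depth_um"].to_numpy(),
            mean_alpha_deg=g["mean_alpha_deg"].to_numpy(),
            n_voxels=g["n"].to_numpy(),
        ))
    return out


# ------------------------------------------------------------------ VTK / CSV

def write_vtk_polylines(path, lines: StreamlineSet) -> None:
    """Streamlines as legacy ASCII VTK polydata with a per-line scalar."""
    pts = [np.asarray(p, dtype=float) for p in lines.polylines]
    n_pts = sum(len(p) for p in pts)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("fibrient streamlines (um; scalar = phi angle deg)\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n_pts} float\n")
        for p in pts:
            for x, y, z in p:
                fh.write(f"{x:.4f} {y:.4f} {z:.4f}\n")
        total = sum(len(p) + 1 for p in pts)
        fh.write(f"LINES {len(pts)} {total}\n")
        off = 0
        for p in pts:
            ids = " ".join(str(off + i) for i in range(len(p)))
            fh.write(f"{len(p)} {ids}\n")
            off += len(p)
        fh.write(f"POINT_DATA {n_pts}\nSCALARS phi_deg float 1\nLOOKUP_TABLE default\n")
        for p, c in zip(pts, lines.color_deg):
            for _ in range(len(p)):
                fh.write(f"{c:.4f}\n")


def write_vtk_glyphs(path, glyphs: GlyphSet) -> None:
    """Glyph samples as VTK vertices with direction vectors and color scalar."""
    pos = glyphs.positions_um
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("fibrient orientation glyphs (um)\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pos)} float\n")
        for x, y, z in pos:
            fh.write(f"{x:.4f} {y:.4f} {z:.4f}\n")
        fh.write(f"VERTICES {len(pos)} {2 * len(pos)}\n")
        for i in range(len(pos)):
            fh.write(f"1 {i}\n")
        fh.write(f"POINT_DATA {len(pos)}\n")
        fh.write("VECTORS orientation float\n")
        for vx, vy, vz in glyphs.directions:
            fh.write(f"{vx:.6f} {vy:.6f} {vz:.6f}\n")
        fh.write("SCALARS angle_deg float 1\nLOOKUP_TABLE default\n")
        for c in glyphs.color_deg:
            fh.write(f"{c:.4f}\n")


# -------------------------------------------------------- config / provenance

def _default_stages() -> dict:
    return {
        "phantom": {"geometry": "helical_annulus", "alpha_profile": [-60.0, 60.0],
                    "outer_layer": None, "shape": [64, 200, 200]},
        "degrade": {"photons": 50.0, "read_noise": 2.0, "attenuation": 0.5},
        "deconv": {"n_iter": 25, "tv_weight": 0.002, "psf_sigma_um": 2.0},
        "denoise": {"n_atoms": 256, "patch_size": [16, 16], "sparsity": 4,
                    "shallow_fraction": 0.25, "stride": 4},
        "stitch": {"overlap_fraction": 0.25, "max_shift_fraction": 0.25},
        "orient": {"sigma_gradient_um": 2.0, "sigma_window_um": 8.0,
                   "fa_floor": 0.1, "degeneracy_floor": 0.05},
        "angles": {"long_axis": [0.0, 0.0, 1.0], "normal_smooth_vox": 10.0},
        "profile": {"wedge_width_deg": 10.0, "wedges_combined": 2,
                    "depth_bin_um": 2.0, "reference_angle_deg": 0.0,
                    "rate_window_voxels": 15},
        "tract": {"n_seeds": 25000, "step_um": 2.0, "max_points": 500,
                  "glyph_stride": 12, "max_vertices": 75000},
    }


@dataclass
class RunConfig:
    """Per-stage parameter blocks with defaults; serialized next to outputs."""

    voxel_size_um: float = 2.0
    seed: int = 0
    out_dir: str = "."
    stages: dict = field(default_factory=_default_stages)

    def merged(self, stage: str, **overrides) -> dict:
        base = dict(_default_stages().get(stage, {}))
        base.update(self.stages.get(stage, {}))
        base.update({k: v for k, v in overrides.items() if v is not None})
        return base

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        cfg.voxel_size_um = float(raw.get("voxel_size_um", cfg.voxel_size_um))
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.out_dir = raw.get("out_dir", cfg.out_dir)
        cfg.stages.update(raw.get("stages", {}))
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Provenance:
    """One record per output file: stage, input hashes, parameters, version."""

    stage: str
    parameters: dict
    inputs: dict = field(default_factory=dict)
    software: str = f"fibrient {_version}"
    timestamp: str = ""

    @classmethod
    def record(cls, stage: str, parameters: dict, input_paths=()) -> "Provenance":
        inputs = {str(p): _sha256(p) for p in input_paths if Path(p).exists()}
        return cls(stage=stage, parameters=parameters, inputs=inputs,
                   timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
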