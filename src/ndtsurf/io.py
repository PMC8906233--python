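"""Point-cloud and CT volume I/O.

PLY support is deliberately minimal: a ``vertex`` element with float ``x``,
``y``, ``z`` properties, in ASCII or binary little-endian form — the subset
optical surface imaging systems emit.  CT series are read with :mod:`pydicom`
and converted to a skin-surface point cloud by thresholding and extracting
boundary voxels.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from scipy import ndimage

from .geometry import as_cloud

__all__ = [
    "PLYFormatError",
    "read_ply",
    "write_ply",
    "CTVolume",
    "read_ct_series",
    "ct_to_surface",
]


class PLYFormatError(ValueError):
    """Raised when a PLY file does not match the supported vertex layout."""


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "float": ("f", 4), "float32": ("f", 4),
    "double": ("d", 8), "float64": ("d", 8),
    "uchar": ("B", 1), "uint8": ("B", 1), "char": ("b", 1), "int8": ("b", 1),
    "short": ("h", 2), "int16": ("h", 2), "ushort": ("H", 2), "uint16": ("H", 2),
    "int": ("i", 4), "int32": ("i", 4), "uint": ("I", 4), "uint32": ("I", 4),
}


def write_ply(cloud, path, *, binary: bool = False) -> None:
    """Write a point cloud as a PLY file with float32 x, y, z properties.

    The default dialect is ASCII; ``binary=True`` writes binary little-endian.
    An empty cloud produces a valid file with vertex count 0.
    """
    pts = as_cloud(cloud).astype(np.float32)
    path = Path(path)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {len(pts)}\n"
        "property float x\n"
        "property float y\n"
        "property float z\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(pts.astype("<f4").tobytes())
        else:
            for p in pts:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n".encode("ascii"))


def read_ply(path) -> np.ndarray:
    """Read a PLY point cloud (ASCII or binary little-endian).

    Only the ``vertex`` element is consumed; its properties must include
    ``x``, ``y``, ``z``.  Extra scalar vertex properties are skipped.

    Raises
    ------
    PLYFormatError
        On a malformed header, truncated body, or unsupported layout; the
        message names the offending header line or byte offset.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        data = fh.read()

    # --- header ---
    end = data.find(b"end_header")
    if not data.startswith(b"ply") or end < 0:
        raise PLYFormatError(f"{path}: not a PLY file (missing 'ply'/'end_header')")
    body_start = data.index(b"\n", end) + 1
    header_lines = data[:end].decode("ascii", "replace").splitlines()

    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    for line in header_lines[1:]:
        tok = line.split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if not elements:
                raise PLYFormatError(f"{path}: property before element: '{line}'")
            if tok[1] == "list":
                raise PLYFormatError(f"{path}: list properties unsupported: '{line}'")
            if tok[1] not in _PLY_TYPES:
                raise PLYFormatError(f"{path}: unknown property type: '{line}'")
            elements[-1][2].append((tok[1], tok[2]))
    if fmt is None:
        raise PLYFormatError(f"{path}: header has no 'format' line")
    if fmt not in ("ascii", "binary_little_endian"):
        raise PLYFormatError(f"{path}: unsupported format '{fmt}'")
    vertex = next((e for e in elements if e[0] == "vertex"), None)
    if vertex is None:
        raise PLYFormatError(f"{path}: no 'element vertex' in header")
    _, count, props = vertex
    names = [n for _, n in props]
    for ax in ("x", "y", "z"):
        if ax not in names:
            raise PLYFormatError(f"{path}: vertex element lacks property '{ax}'")
    if elements.index(vertex) != 0:
        raise PLYFormatError(f"{path}: vertex must be the first element")
    cols = [names.index(ax) for ax in ("x", "y", "z")]

    # --- body ---
    if fmt == "ascii":
        text = data[body_start:].decode("ascii", "replace").split()
        need = count * len(props)
        if len(text) < need:
            raise PLYFormatError(
                f"{path}: truncated body ({len(text)} values, expected {need})")
        vals = np.array(text[:need], dtype=float).reshape(count, len(props))
        return np.ascontiguousarray(vals[:, cols], dtype=float)
    # binary little-endian, possibly heterogeneous property types
    fmts = [_PLY_TYPES[t][0] for t, _ in props]
    rec = struct.Struct("<" + "".join(fmts))
    need = count * rec.size
    if len(data) - body_start < need:
        raise PLYFormatError(
            f"{path}: truncated body at byte {len(data)} (expected {body_start + need})")
    out = np.empty((count, 3), dtype=float)
    for i, row in enumerate(rec.iter_unpack(data[body_start:body_start + need])):
        out[i] = [row[cols[0]], row[cols[1]], row[cols[2]]]
    return out


# ---------------------------------------------------------------------------
# CT
# ---------------------------------------------------------------------------

@dataclass
class CTVolume:
    """A CT volume on a regular grid.

    ``voxels[i, j, k]`` holds the intensity (HU) at physical position
    ``origin + (i * pixel_pitch, j * pixel_pitch, k * slice_spacing)`` —
    voxel centres, 0-based indices, mm.  Axis mapping from DICOM: i runs
    along image columns (DICOM x), j along image rows (DICOM y), k across
    slices sorted by table position (DICOM z).
    """

    voxels: np.ndarray
    pixel_pitch: float
    slice_spacing: float
    origin: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if self.pixel_pitch <= 0 or self.slice_spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def spacing(self) -> np.ndarray:
        return np.array([self.pixel_pitch, self.pixel_pitch, self.slice_spacing])

    def index_to_mm(self, indices) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * self.spacing + self.origin


def read_ct_series(directory) -> CTVolume:
    """Read a directory of single-frame CT slices into a :class:`CTVolume`.

    Slices are sorted by table position (ImagePositionPatient z), intensities
    are rescaled to HU with RescaleSlope/Intercept, and slice gaps must be
    uniform to within 1%.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue  # non-DICOM files in the directory are ignored
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if len(slices) < 2:
        raise ValueError(f"{directory}: need at least 2 CT slices, found {len(slices)}")
    series = {getattr(s, "SeriesInstanceUID", None) for s in slices}
    if len(series) > 1:
        raise ValueError(f"{directory}: mixed series ({len(series)} SeriesInstanceUIDs)")
    for s in slices:
        if not hasattr(s, "PixelSpacing") or not hasattr(s, "ImagePositionPatient"):
            raise ValueError(f"{directory}: slice lacks PixelSpacing/ImagePositionPatient")

    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    gaps = np.diff(zs)
    if gaps.min() <= 0:
        raise ValueError(f"{directory}: duplicate or non-monotone slice positions")
    mean_gap = gaps.mean()
    if (np.abs(gaps - mean_gap) / mean_gap).max() > 0.01:
        raise ValueError(
            f"{directory}: non-uniform slice spacing (gaps {gaps.min():.3f}"
            f"-{gaps.max():.3f} mm differ by more than 1%)")

    ps = [float(v) for v in slices[0].PixelSpacing]
    if abs(ps[0] - ps[1]) > 1e-6 * max(ps):
        raise ValueError(f"{directory}: anisotropic in-plane pixel spacing {ps}")

    planes = []
    for s in slices:
        arr = s.pixel_array.astype(float)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # pixel_array is (rows, cols) = (j, i); volume wants [i, j, k]
    vol = np.stack([p.T for p in planes], axis=2)
    ipp = [float(v) for v in slices[0].ImagePositionPatient]
    return CTVolume(vol, pixel_pitch=ps[0], slice_spacing=float(mean_gap),
                    origin=np.array(ipp))


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def ct_to_surface(volume: CTVolume, threshold: float = -300.0) -> np.ndarray:
    """Convert a CT volume into a surface point cloud.

    Three steps: (1) binarise at ``threshold`` (voxel >= threshold is
    foreground), (2) mark contour voxels — foreground voxels with at least
    one background 6-neighbour (volume borders count as background) — into a
    binary cube, (3) emit each contour voxel's centre in mm.

    The default threshold of -300 HU separates soft tissue from air for
    body-surface extraction.
    """
    fg = volume.voxels >= threshold
    if not fg.any():
        raise ValueError("empty surface: no voxel reaches the threshold")
    interior = ndimage.binary_erosion(fg, structure=_FACE_STRUCTURE,
                                      border_value=0)
    boundary = fg & ~interior
    idx = np.argwhere(boundary)
    return volume.index_to_mm(idx)
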