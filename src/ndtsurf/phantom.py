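"""Synthetic torso-phantom generator.

Emulates the accuracy-evaluation setup: a rigid torso-shaped phantom on a
treatment couch, imaged from above by ceiling-mounted depth cameras, with
known couch shifts as ground truth, plus a coarse CT volume of the same
phantom for the CT-to-surface path.

The torso is a tapered superellipse cylinder: cross-section
``|x/a|^e + |z/b|^e = 1`` (exponent 2.5) extruded along y with the
half-axes shrinking linearly from chest (y = 0) to waist (y = length), so
that every translation axis is observable from the shape alone.  It rests
on the couch plane z = 0 with its upper half exposed.  A cube phantom is embedded
for target-accuracy experiments; the treatment target is its centre.  All
randomness is driven by explicit seeds — same seed, same output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidTransform, as_cloud
from .io import CTVolume

__all__ = ["PhantomSpec", "CaptureSpec", "generate_torso_surface",
           "simulate_capture", "generate_ct_volume", "write_dicom_series"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic torso phantom.

    half_width / half_height are the chest superellipse half-axes a
    (lateral, mm) and b (vertical, mm); length runs longitudinally and the
    half-axes shrink by the fraction ``taper`` from chest to waist.  The
    embedded cube is centred laterally and longitudinally; its centre is
    the treatment target.  density is the surface sampling density in
    points/mm^2.
    """

    half_width: float = 300.0
    half_height: float = 200.0
    length: float = 600.0
    exponent: float = 2.5
    taper: float = 0.25
    cube_size: tuple = (450.0, 450.0, 400.0)
    density: float = 0.01

    def __post_init__(self):
        if min(self.half_width, self.half_height, self.length,
               self.exponent, self.density) <= 0 or min(self.cube_size) <= 0:
            raise ValueError("phantom dimensions must be positive")
        if not 0.0 <= self.taper < 1.0:
            raise ValueError("taper must lie in [0, 1)")

    def scale_at(self, y):
        """Cross-section scale factor at longitudinal position y."""
        return 1.0 - self.taper * np.clip(np.asarray(y, dtype=float)
                                          / self.length, 0.0, 1.0)

    @property
    def target_point(self) -> np.ndarray:
        """Centre of the embedded cube phantom (the planned target), mm."""
        return np.array([0.0, self.length / 2.0, self.cube_size[2] / 2.0])

    def profile(self, theta):
        """Upper-surface cross-section point(s) at parameter angle theta."""
        theta = np.asarray(theta, dtype=float)
        c, s = np.cos(theta), np.sin(theta)
        x = self.half_width * np.sign(c) * np.abs(c) ** (2.0 / self.exponent)
        z = self.half_height * np.abs(s) ** (2.0 / self.exponent)
        return x, z

    def inside(self, points) -> np.ndarray:
        """Mask of points inside the solid phantom (upper half, z >= 0)."""
        pts = as_cloud(points)
        x, y, z = pts.T
        s = self.scale_at(y)
        body = (np.abs(x / (self.half_width * s)) ** self.exponent
                + np.abs(z / (self.half_height * s)) ** self.exponent) <= 1.0
        return body & (z >= 0) & (y >= 0) & (y <= self.length)


@dataclass(frozen=True)
class CaptureSpec:
    """One simulated optical capture of the phantom.

    shift is the couch displacement applied to the phantom (mm); rotation
    an optional small couch rotation (degrees).  noise_sigma is the
    per-point capture noise (default 0.5 mm).  visible_fraction keeps the
    uppermost fraction of the cloud's own height range, emulating
    ceiling-camera visibility; dropout_rate drops points at random.
    """

    shift: tuple = (0.0, 0.0, 0.0)
    rotation_deg: tuple = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.5
    visible_fraction: float = 0.6
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 < self.visible_fraction <= 1.0:
            raise ValueError("visible_fraction must lie in (0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def pose(self) -> RigidTransform:
        return RigidTransform(np.asarray(self.shift, dtype=float),
                              np.asarray(self.rotation_deg, dtype=float))


def _arc_table(spec: PhantomSpec, n: int = 2048):
    """Cumulative arc length of the upper profile, for uniform-in-arc sampling."""
    theta = np.linspace(0.0, np.pi, n)
    x, z = spec.profile(theta)
    seg = np.hypot(np.diff(x), np.diff(z))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return theta, cum


def generate_torso_surface(spec: PhantomSpec = PhantomSpec(),
                           seed: int = 0) -> np.ndarray:
    """Quasi-uniform point sample of the torso's upper surface.

    The point count is surface area (arc length x length) times
    ``spec.density``; positions are drawn uniformly in arc length and in y,
    from a generator seeded with ``seed``.
    """
    theta_tab, cum = _arc_table(spec)
    area = cum[-1] * spec.length
    n = int(round(area * spec.density))
    rng = np.random.default_rng(seed)
    s = rng.uniform(0.0, cum[-1], n)
    theta = np.interp(s, cum, theta_tab)
    x, z = spec.profile(theta)
    y = rng.uniform(0.0, spec.length, n)
    sc = spec.scale_at(y)
    return np.column_stack([x * sc, y, z * sc])


def simulate_capture(cloud, capture: CaptureSpec) -> np.ndarray:
    """Simulate one depth-camera capture of a (possibly shifted) phantom.

    Steps, in order: rigid couch shift/rotation, visibility culling (keep
    the top ``visible_fraction`` of the cloud's own height range), iid
    Gaussian noise, random dropout.  Deterministic for a fixed seed.
    """
    pts = capture.pose.apply(as_cloud(cloud))
    rng = np.random.default_rng(capture.seed)
    if capture.visible_fraction < 1.0:
        z = pts[:, 2]
        lo, hi = z.min(), z.max()
        cut = hi - capture.visible_fraction * (hi - lo)
        pts = pts[z >= cut]
    if capture.noise_sigma > 0:
        pts = pts + rng.normal(0.0, capture.noise_sigma, pts.shape)
    if capture.dropout_rate > 0:
        pts = pts[rng.random(len(pts)) >= capture.dropout_rate]
    return pts


def generate_ct_volume(spec: PhantomSpec = PhantomSpec(),
                       pitch: float = 4.0,
                       slice_spacing: float | None = None,
                       margin: float = 8.0) -> CTVolume:
    """Voxelise the solid phantom into a binary-intensity CT volume.

    Foreground voxels (value 1) are those whose centre lies inside the
    solid torso; the volume is padded with ``margin`` mm of background on
    every side so the full surface is recoverable by boundary extraction
    (threshold 0.5).
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    dz = slice_spacing if slice_spacing is not None else pitch
    lo = np.array([-spec.half_width, 0.0, 0.0]) - margin
    hi = np.array([spec.half_width, spec.length, spec.half_height]) + margin
    spacing = np.array([pitch, pitch, dz])
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    centers = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) * spacing + lo
    vox = spec.inside(centers).astype(np.float32).reshape(tuple(shape))
    return CTVolume(vox, pixel_pitch=pitch, slice_spacing=dz, origin=lo)


def write_dicom_series(volume: CTVolume, directory, *,
                       series_uid: str | None = None) -> list:
    """Write a :class:`CTVolume` as a directory of single-frame CT slices.

    Intended for exercising the DICOM reading path with synthetic data;
    intensities are stored with RescaleIntercept -1000 so a binary 0/1
    volume survives the uint16 pixel representation.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    intercept = -1000.0
    paths = []
    nx, ny, nz = volume.voxels.shape
    for k in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [f"{volume.pixel_pitch:g}", f"{volume.pixel_pitch:g}"]
        ds.SliceThickness = f"{volume.slice_spacing:g}"
        ds.ImagePositionPatient = [
            f"{volume.origin[0]:g}", f"{volume.origin[1]:g}",
            f"{volume.origin[2] + k * volume.slice_spacing:g}"]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = f"{intercept:g}"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        plane = volume.voxels[:, :, k].T  # (rows, cols) = (j, i)
        ds.PixelData = (plane - intercept).astype(np.uint16).tobytes()
        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
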