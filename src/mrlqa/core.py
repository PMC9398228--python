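"""Core data carriers shared by every analysis stage.

Coordinate convention (used everywhere in this package): machine/patient
coordinates are in millimetres with the origin at the scanner isocenter.
Arrays are indexed ``voxels[ix, iy, iz]``; the world position of a voxel
center is ``origin_mm + index * spacing_mm``.  By default volumes are
centered on the isocenter, i.e. ``origin_mm = -(shape - 1) / 2 * spacing_mm``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionSpec",
    "ImageVolume",
    "RoiSpec",
    "InvalidSpecError",
    "GAMMA_MHZ_PER_T",
    "save_nifti",
    "load_nifti",
]

#: Proton gyromagnetic ratio in MHz/T.
GAMMA_MHZ_PER_T = 42.577478518


class InvalidSpecError(ValueError):
    """An acquisition/phantom specification violates its invariants."""


@dataclass
class AcquisitionSpec:
    """Acquisition metadata attached to every image volume.

    Attributes
    ----------
    tr_ms : float
        Repetition time in milliseconds.
    te_ms_list : list of float
        Echo times in milliseconds (one per echo).
    flip_angles_deg : list of float
        Flip angles in degrees (one per volume in a variable-flip-angle run).
    b_values_s_per_mm2 : list of float
        Diffusion weightings in s/mm^2.
    voxel_size_mm, matrix :
        Voxel spacing (mm) and matrix size along (x, y, z).
    gantry_angle_deg : float
        Treatment-gantry angle at acquisition time.
    field_T, gamma_MHz_per_T :
        Nominal static field and gyromagnetic ratio; the nominal resonance
        frequency is their product.
    """

    tr_ms: float = 1000.0
    te_ms_list: list = field(default_factory=lambda: [30.0])
    flip_angles_deg: list = field(default_factory=lambda: [90.0])
    b_values_s_per_mm2: list = field(default_factory=list)
    voxel_size_mm: tuple = (1.2, 1.2, 5.0)
    matrix: tuple = (200, 200, 1)
    gantry_angle_deg: float = 0.0
    field_T: float = 1.5
    gamma_MHz_per_T: float = GAMMA_MHZ_PER_T

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidSpecError("voxel size must be strictly positive")
        if any(int(m) <= 0 for m in self.matrix):
            raise InvalidSpecError("matrix must be strictly positive")
        if self.te_ms_list and self.tr_ms <= max(self.te_ms_list):
            raise InvalidSpecError("TR must exceed every TE")
        if any(b < 0 for b in self.b_values_s_per_mm2):
            raise InvalidSpecError("b-values must be non-negative")
        if any(not (0.0 < a <= 90.0) for a in self.flip_angles_deg):
            raise InvalidSpecError("flip angles must lie in (0, 90] degrees")

    @property
    def nominal_f0_MHz(self) -> float:
        return self.gamma_MHz_per_T * self.field_T

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        d["matrix"] = [int(m) for m in self.matrix]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSpec":
        d = dict(d)
        d["voxel_size_mm"] = tuple(d.get("voxel_size_mm", (1.2, 1.2, 5.0)))
        d["matrix"] = tuple(d.get("matrix", (200, 200, 1)))
        return cls(**d)


@dataclass
class ImageVolume:
    """A scalar image volume with spatial metadata.

    ``voxels`` holds magnitude in arbitrary units, or phase in radians when
    ``is_phase`` is set (phase is kept wrapped to (-pi, pi]).
    """

    voxels: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = None
    meta: AcquisitionSpec = None
    is_phase: bool = False
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[:, :, None]
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        if self.spacing_mm.size == 2:
            self.spacing_mm = np.append(self.spacing_mm, 1.0)
        if np.any(self.spacing_mm <= 0):
            raise InvalidSpecError("spacing must be strictly positive")
        if self.origin_mm is None:
            self.origin_mm = -(np.array(self.voxels.shape) - 1) / 2.0 * self.spacing_mm
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.is_phase:
            v = self.voxels
            if v.size and (v.min() <= -np.pi - 1e-9 or v.max() > np.pi + 1e-9):
                raise InvalidSpecError("phase volumes must be wrapped to (-pi, pi]")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.asarray(idx, dtype=float) * self.spacing_mm

    def mm_to_index(self, mm: np.ndarray) -> np.ndarray:
        return (np.asarray(mm, dtype=float) - self.origin_mm) / self.spacing_mm

    def coordinate_grids(self):
        """World-coordinate (x, y, z) arrays broadcastable to ``voxels``."""
        nx, ny, nz = self.voxels.shape
        x = self.origin_mm[0] + np.arange(nx) * self.spacing_mm[0]
        y = self.origin_mm[1] + np.arange(ny) * self.spacing_mm[1]
        z = self.origin_mm[2] + np.arange(nz) * self.spacing_mm[2]
        return (
            x[:, None, None],
            y[None, :, None],
            z[None, None, :],
        )


@dataclass
class RoiSpec:
    """A circular or rectangular region of interest in machine coordinates.

    Circles are defined in the x-y plane (``center_mm`` may carry a third
    component selecting a slice neighbourhood); rectangles by full extents.
    """

    shape: str = "circle"
    center_mm: tuple = (0.0, 0.0)
    diameter_mm: float = None
    extents_mm: tuple = None

    def __post_init__(self):
        if self.shape not in ("circle", "rectangle"):
            raise InvalidSpecError(f"unknown ROI shape {self.shape!r}")
        if self.shape == "circle" and (self.diameter_mm is None or self.diameter_mm <= 0):
            raise InvalidSpecError("circular ROI requires a positive diameter")
        if self.shape == "rectangle" and self.extents_mm is None:
            raise InvalidSpecError("rectangular ROI requires extents")

    def mask(self, vol: ImageVolume) -> np.ndarray:
        """Boolean mask of the ROI on the volume's grid (all slices)."""
        x, y, _ = vol.coordinate_grids()
        cx, cy = self.center_mm[0], self.center_mm[1]
        if self.shape == "circle":
            r = self.diameter_mm / 2.0
            m2 = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
        else:
            ex, ey = self.extents_mm[0] / 2.0, self.extents_mm[1] / 2.0
            m2 = (np.abs(x - cx) <= ex) & (np.abs(y - cy) <= ey)
        mask = np.broadcast_to(m2, vol.voxels.shape).copy()
        if not mask.any():
            raise InvalidSpecError("ROI lies outside the image bounds")
        return mask

    def values(self, vol: ImageVolume) -> np.ndarray:
        return vol.voxels[self.mask(vol)]


def _affine(vol: ImageVolume) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vol.spacing_mm)
    aff[:3, 3] = vol.origin_mm
    return aff


def save_nifti(vol: ImageVolume, path: str | Path, sidecar: dict | None = None) -> Path:
    """Write a volume as uncompressed NIfTI plus an optional JSON sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), _affine(vol)), str(path))
    side = {} if sidecar is None else dict(sidecar)
    if vol.meta is not None:
        side.setdefault("acquisition", vol.meta.to_dict())
    side.setdefault("is_phase", vol.is_phase)
    if vol.flags:
        side.setdefault("flags", dict(vol.flags))
    if side:
        path.with_suffix(".json").write_text(json.dumps(side, indent=1, sort_keys=True))
    return path


def load_nifti(path: str | Path) -> ImageVolume:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    aff = img.affine
    spacing = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3]
    meta = None
    is_phase = False
    flags = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        is_phase = bool(side.get("is_phase", False))
        flags = dict(side.get("flags", {}))
        if "acquisition" in side:
            meta = AcquisitionSpec.from_dict(side["acquisition"])
    return ImageVolume(data, spacing, origin, meta=meta, is_phase=is_phase, flags=flags)
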