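"""Volume/mask containers, NRRD I/O and mask propagation.

All volumes are stored index-ordered ``(slice, row, column)`` — i.e. numpy
axis 0 is the slice (z) axis — with per-axis spacing in millimetres in the
same order.  This is the array layout SimpleITK produces via
``GetArrayFromImage`` and is asserted everywhere; SimpleITK's own
``(x, y, z)`` metadata order is reversed at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

logger = logging.getLogger("dceradiomics")

AXIS_ORDER = "zyx"
ROI_LABELS = ("tumor", "healthy", "vessel")


class GeometryError(ValueError):
    """Shape/spacing/origin mismatch between a volume and a mask or series."""


@dataclass
class ImageVolume:
    """A single 3D scalar volume (HU for CT, arbitrary units for MR)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"expected 3 dimensions, got {self.voxels.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive on all axes: {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        if self.axis_order != AXIS_ORDER:
            raise ValueError(f"axis order must be {AXIS_ORDER!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.voxels)
        img.SetSpacing(tuple(reversed(self.spacing)))
        img.SetOrigin(tuple(reversed(self.origin)))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        arr = sitk.GetArrayFromImage(img)
        return cls(
            voxels=arr,
            spacing=tuple(reversed(img.GetSpacing())),
            origin=tuple(reversed(img.GetOrigin())),
        )

    def geometry_equal(self, other, atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class RoiMask:
    """Binary region-of-interest mask sharing geometry with a reference volume."""

    voxels: np.ndarray
    label: str
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {self.voxels.ndim}")
        if self.label not in ROI_LABELS:
            raise ValueError(f"label must be one of {ROI_LABELS}, got {self.label!r}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on all axes")
        if not self.voxels.any():
            raise ValueError("empty ROI: mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def geometry_equal(self, other, atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class DynamicSeries:
    """Ordered 3D volumes acquired after contrast injection."""

    volumes: list[ImageVolume]
    acquisition_times: np.ndarray
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.acquisition_times = np.asarray(self.acquisition_times, dtype=float)
        if len(self.volumes) < 7:
            raise ValueError("a dynamic series needs at least 7 volumes")
        if len(self.volumes) != len(self.acquisition_times):
            raise ValueError("one acquisition time per volume required")
        if np.any(np.diff(self.acquisition_times) <= 0):
            raise ValueError("acquisition times must be strictly increasing")
        if self.modality not in ("CT", "MR"):
            raise ValueError("modality must be 'CT' or 'MR'")
        ref = self.volumes[0]
        for i, vol in enumerate(self.volumes[1:], start=1):
            if not ref.geometry_equal(vol):
                raise GeometryError(f"volume {i} geometry differs from volume 0")

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape


# ---------------------------------------------------------------------------
# NRRD I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> ImageVolume:
    """Read a 3D NRRD volume.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` if
    the payload is not three-dimensional or spacing metadata is unusable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected 3 dimensions, got {img.GetDimension()}")
    if any(s <= 0 for s in img.GetSpacing()):
        raise ValueError("missing or non-positive spacing metadata")
    return ImageVolume.from_sitk(img)


def write_volume(path, volume: ImageVolume) -> None:
    """Write a volume as NRRD; integer arrays round-trip bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(volume.to_sitk(), str(path), useCompression=False)


def read_mask(path, label: str) -> RoiMask:
    vol = read_volume(path)
    return RoiMask(voxels=vol.voxels > 0, label=label, spacing=vol.spacing, origin=vol.origin)


def write_mask(path, mask: RoiMask) -> None:
    vol = ImageVolume(
        voxels=mask.voxels.astype(np.uint8), spacing=mask.spacing, origin=mask.origin
    )
    write_volume(path, vol)


# ---------------------------------------------------------------------------
# Mask propagation
# ---------------------------------------------------------------------------

def propagate_mask(mask: RoiMask, series: DynamicSeries) -> list[RoiMask]:
    """Copy a mask onto every volume of a same-geometry dynamic series.

    Series acquired in one session share the scanner grid, so propagation is
    an identity copy; the geometry-equality precondition replaces any visual
    check.  Raises :class:`GeometryError` naming the first mismatched axis.
    """
    if not mask.voxels.any():
        raise ValueError("empty ROI: mask has no foreground voxels")
    ref = series.volumes[0]
    for axis in range(3):
        if mask.shape[axis] != ref.shape[axis]:
            raise GeometryError(
                f"mask/series shape mismatch on axis {axis} ({AXIS_ORDER[axis]}): "
                f"{mask.shape[axis]} vs {ref.shape[axis]}"
            )
        if not np.isclose(mask.spacing[axis], ref.spacing[axis]):
            raise GeometryError(
                f"mask/series spacing mismatch on axis {axis} ({AXIS_ORDER[axis]}): "
                f"{mask.spacing[axis]} vs {ref.spacing[axis]}"
            )
    return [replace(mask, voxels=mask.voxels.copy()) for _ in series.volumes]


# ---------------------------------------------------------------------------
# Run configuration and logging
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration file must contain a mapping")
    return cfg


def save_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def setup_logging(level: str = "INFO", logfile=None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
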