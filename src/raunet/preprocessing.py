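"""CT volume I/O and intensity preprocessing.

Volumes are held as ``(x, y, z)`` arrays of Hounsfield units (z axial) with
per-axis voxel spacing in millimetres and a grid-to-world affine, the
native layout of NIfTI images as read by nibabel.

Preprocessing is a global Hounsfield window (default −100..200 HU, wide
enough to keep liver parenchyma at 40–50 HU and hypodense lesions while
clamping air and bone) followed by zero-mean and min-max normalization, so
network inputs always lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

from .errors import DegenerateVolumeError, ShapeError


@dataclass
class Volume:
    """A 3D scalar grid (HU or probability) with geometry metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"Volume requires a 3D grid, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ShapeError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ShapeError(f"spacing must be positive, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same geometry, new voxel values."""
        return replace(self, data=data)


@dataclass(frozen=True)
class WindowConfig:
    """Hounsfield window bounds."""

    hu_min: float = -100.0
    hu_max: float = 200.0

    def __post_init__(self):
        if not self.hu_min < self.hu_max:
            raise ValueError(f"hu_min must be < hu_max, got [{self.hu_min}, {self.hu_max}]")


def read_volume(path) -> Volume:
    """Read a 3D NIfTI file; voxel values and geometry are unmodified."""
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise IOError(f"cannot read NIfTI file: {path}") from None
    except Exception as exc:
        raise IOError(f"cannot read NIfTI file: {path} ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3D image, got {data.ndim}D shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(v: Volume, path, dtype=None) -> None:
    data = v.data if dtype is None else v.data.astype(dtype)
    img = nib.Nifti1Image(data, v.affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def window_hu(v: Volume, w: WindowConfig = WindowConfig()) -> Volume:
    """Clip every voxel to [hu_min, hu_max]; geometry unchanged."""
    return v.with_data(np.clip(v.data, w.hu_min, w.hu_max))


def normalize(v: Volume) -> Volume:
    """Zero-mean then min-max rescale so the output range is exactly [0, 1]."""
    x = v.data.astype(np.float64)
    x = x - x.mean()
    lo, hi = x.min(), x.max()
    if hi - lo == 0:
        raise DegenerateVolumeError(
            "cannot min-max normalize a constant volume (zero intensity range)"
        )
    return v.with_data(((x - lo) / (hi - lo)).astype(np.float32))


def preprocess(v: Volume, w: WindowConfig = WindowConfig()) -> Volume:
    """The standard chain: HU window, then normalization to [0, 1]."""
    return normalize(window_hu(v, w))
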