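"""The three-stage coarse-to-fine inference cascade.

Stage I localizes the liver with the 2D network: every axial slice is
resized to 256×256, segmented, restacked, connected-component filtered, and
the surviving component's bounding box is expanded by a 10-voxel safety
margin.  Stage II segments the liver inside that box with the 3D network on
overlapping 224×224×32 windows after in-plane resizing to 224×224; window
probabilities are fused by voxelwise averaging, thresholded at 0.5, and
reduced to the largest connected component.  Stage III tiles 128×128×32
windows at native resolution over the liver region, fuses and thresholds
the tumor probabilities, and clears everything outside the liver mask
(multiple tumor components are allowed).

Connectivity is the full 26-neighbourhood throughout; image and probability
interpolation is linear, mask interpolation nearest-neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptySegmentationError, ShapeError
from .preprocessing import Volume
from .training import ensemble_predict

FULL_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)  # 26-neighbourhood


@dataclass(frozen=True)
class BoundaryBox:
    """Axis-aligned 3D region with inclusive voxel index ranges."""

    x0: int
    x1: int
    y0: int
    y1: int
    z0: int
    z1: int

    def __post_init__(self):
        for lo, hi, name in ((self.x0, self.x1, "x"), (self.y0, self.y1, "y"),
                             (self.z0, self.z1, "z")):
            if lo > hi or lo < 0:
                raise ShapeError(f"invalid {name} range [{lo}, {hi}]")

    @property
    def axial_length(self) -> int:
        """M: the number of axial slices covered."""
        return self.z1 - self.z0 + 1

    def shape(self) -> tuple[int, int, int]:
        return (self.x1 - self.x0 + 1, self.y1 - self.y0 + 1, self.axial_length)

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(self.x0, self.x1 + 1), slice(self.y0, self.y1 + 1),
                slice(self.z0, self.z1 + 1))

    def expand(self, margin: int, volume_shape: tuple[int, int, int]) -> "BoundaryBox":
        """Grow by `margin` voxels per direction, clamped to the volume."""
        nx, ny, nz = volume_shape
        return BoundaryBox(
            max(self.x0 - margin, 0), min(self.x1 + margin, nx - 1),
            max(self.y0 - margin, 0), min(self.y1 + margin, ny - 1),
            max(self.z0 - margin, 0), min(self.z1 + margin, nz - 1),
        )

    def contains(self, other: "BoundaryBox") -> bool:
        return (self.x0 <= other.x0 and other.x1 <= self.x1
                and self.y0 <= other.y0 and other.y1 <= self.y1
                and self.z0 <= other.z0 and other.z1 <= self.z1)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "BoundaryBox":
        coords = np.argwhere(mask)
        if coords.size == 0:
            raise EmptySegmentationError("boundary-box", "cannot box an empty mask")
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        return cls(int(lo[0]), int(hi[0]), int(lo[1]), int(hi[1]), int(lo[2]), int(hi[2]))

    def to_dict(self) -> dict:
        return {"x0": self.x0, "x1": self.x1, "y0": self.y0, "y1": self.y1,
                "z0": self.z0, "z1": self.z1}


@dataclass
class SegmentationResult:
    """Everything the cascade produces for one input volume."""

    box: BoundaryBox
    liver_mask: np.ndarray
    tumor_mask: np.ndarray
    liver_probability: np.ndarray
    tumor_probability: np.ndarray


def largest_component(mask: np.ndarray, connectivity: np.ndarray | None = None,
                      stage: str = "postprocess") -> np.ndarray:
    """Keep only the connected component with the most voxels (26-connected)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptySegmentationError(stage)
    if connectivity is None:
        connectivity = np.ones((3,) * mask.ndim, dtype=bool)
    labels, n = ndimage.label(mask, structure=connectivity)
    if n == 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(counts.argmax())


def _zoom_to(data: np.ndarray, target: tuple[int, ...], order: int) -> np.ndarray:
    factors = tuple(t / s for t, s in zip(target, data.shape))
    out = ndimage.zoom(data, factors, order=order, grid_mode=True, mode="grid-constant")
    if out.shape != tuple(target):  # guard against rounding in ndimage.zoom
        sl = tuple(slice(0, t) for t in target)
        out = out[sl]
        pads = [(0, t - s) for t, s in zip(target, out.shape)]
        if any(p[1] for p in pads):
            out = np.pad(out, pads)
    return out


def _as_models(model) -> list:
    return list(model) if isinstance(model, (list, tuple)) else [model]


def localize_liver(
    v: Volume,
    model2d,
    threshold: float = 0.5,
    margin: int = 10,
    slice_size: int = 256,
    batch_size: int = 8,
) -> BoundaryBox:
    """Stage I: coarse liver boundary box from slice-wise 2D segmentation.

    Expects a preprocessed (windowed + normalized) volume.
    """
    models = _as_models(model2d)
    nx, ny, nz = v.data.shape
    slices = np.empty((nz, slice_size, slice_size, 1), dtype=np.float32)
    for z in range(nz):
        slices[z, ..., 0] = _zoom_to(v.data[:, :, z].astype(np.float32),
                                     (slice_size, slice_size), order=1)
    probs = np.empty_like(slices)
    for i in range(0, nz, batch_size):
        probs[i:i + batch_size] = ensemble_predict(models, slices[i:i + batch_size])
    coarse = probs[..., 0] >= threshold  # (z, x, y), stacked in original order
    coarse = np.moveaxis(coarse, 0, -1)  # back to (x, y, z)
    if not coarse.any():
        raise EmptySegmentationError("liver-localization")
    coarse = largest_component(coarse, stage="liver-localization")
    native = _zoom_to(coarse.astype(np.uint8), (nx, ny, nz), order=0).astype(bool)
    if not native.any():
        raise EmptySegmentationError("liver-localization")
    return BoundaryBox.from_mask(native).expand(margin, v.data.shape)


def merge_patch_probabilities(
    patches: list[np.ndarray],
    positions: list[tuple[int, ...]],
    out_shape: tuple[int, ...],
) -> np.ndarray:
    """Fuse overlapping window probabilities by voxelwise averaging.

    Each voxel receives the mean of all windows covering it; uncovered
    voxels stay 0.
    """
    acc = np.zeros(out_shape, dtype=np.float64)
    cover = np.zeros(out_shape, dtype=np.int32)
    for patch, pos in zip(patches, positions):
        patch = np.asarray(patch)
        sl = tuple(slice(p, p + s) for p, s in zip(pos, patch.shape))
        if any(p < 0 or p + s > o for p, s, o in zip(pos, patch.shape, out_shape)):
            raise ShapeError(f"patch at {pos} with shape {patch.shape} "
                             f"exceeds output grid {out_shape}")
        acc[sl] += patch
        cover[sl] += 1
    np.divide(acc, cover, out=acc, where=cover > 0)
    return acc.astype(np.float32)


def _window_starts(extent: int, window: int, stride: int) -> list[int]:
    """Start offsets covering [0, extent) with a flush final window."""
    if extent <= window:
        return [0]
    starts = list(range(0, extent - window + 1, stride))
    if starts[-1] != extent - window:
        starts.append(extent - window)
    return starts


def segment_liver(
    v: Volume,
    box: BoundaryBox,
    model3d,
    window_shape: tuple[int, int, int] = (224, 224, 32),
    stride_z: int = 16,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Stage II: liver mask + probability volume from the boundary box.

    The box is resized in-plane to the window's in-plane size, tiled with
    overlapping axial windows, ensemble-predicted, fused by averaging,
    resized back to the native box grid, thresholded, and reduced to the
    largest connected component.  Returns full-volume (mask, probability).
    """
    models = _as_models(model3d)
    wx, wy, wz = window_shape
    crop = v.data[box.slices()].astype(np.float32)
    m = crop.shape[2]
    work = _zoom_to(crop, (wx, wy, m), order=1)
    valid_z = m
    if m < wz:
        work = np.pad(work, ((0, 0), (0, 0), (0, wz - m)))
        m = wz
    patches, positions = [], []
    for z0 in _window_starts(m, wz, stride_z):
        pred = ensemble_predict(models, work[:, :, z0:z0 + wz])
        patches.append(pred)
        positions.append((0, 0, z0))
    prob_work = merge_patch_probabilities(patches, positions, (wx, wy, m))
    prob_work = prob_work[:, :, :valid_z]
    prob_box = _zoom_to(prob_work, crop.shape, order=1)
    mask_box = prob_box >= threshold
    if not mask_box.any():
        raise EmptySegmentationError("liver-segmentation")
    mask_box = largest_component(mask_box, stage="liver-segmentation")
    full_mask = np.zeros(v.data.shape, dtype=bool)
    full_mask[box.slices()] = mask_box
    full_prob = np.zeros(v.data.shape, dtype=np.float32)
    full_prob[box.slices()] = np.clip(prob_box, 0.0, 1.0)
    return full_mask, full_prob


def segment_tumor(
    v: Volume,
    liver_mask: np.ndarray,
    model3d,
    window_shape: tuple[int, int, int] = (128, 128, 32),
    stride: tuple[int, int, int] = (64, 64, 16),
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Stage III: tumor mask inside the liver, at native resolution.

    No resizing; overlapping windows tile the liver region, fused
    probabilities are thresholded and every voxel outside the liver mask is
    cleared.  An empty tumor mask is a valid output.  Returns full-volume
    (mask, probability).
    """
    models = _as_models(model3d)
    if not np.asarray(liver_mask).any():
        raise EmptySegmentationError("tumor-extraction", "empty liver mask")
    region = BoundaryBox.from_mask(liver_mask)
    shape = v.data.shape
    ws = window_shape
    # clamp window starts so windows stay inside the volume even when the
    # liver region is smaller than the window
    starts_per_axis = []
    for axis, (lo, hi) in enumerate(((region.x0, region.x1), (region.y0, region.y1),
                                     (region.z0, region.z1))):
        extent = hi - lo + 1
        local = _window_starts(extent, ws[axis], stride[axis])
        full = sorted({min(max(lo + s, 0), shape[axis] - ws[axis]) for s in local})
        starts_per_axis.append(full)
    patches, positions = [], []
    for x0 in starts_per_axis[0]:
        for y0 in starts_per_axis[1]:
            for z0 in starts_per_axis[2]:
                win = v.data[x0:x0 + ws[0], y0:y0 + ws[1], z0:z0 + ws[2]].astype(np.float32)
                patches.append(ensemble_predict(models, win))
                positions.append((x0, y0, z0))
    prob = merge_patch_probabilities(patches, positions, shape)
    mask = (prob >= threshold) & liver_mask.astype(bool)
    prob = prob * liver_mask.astype(np.float32)
    return mask, prob


@dataclass
class CascadeModels:
    """The three trained models (or ensembles) the cascade composes."""

    localizer_2d: object
    liver_3d: object
    tumor_3d: object


def run_cascade(
    v: Volume,
    models: CascadeModels,
    liver_window: tuple[int, int, int] = (224, 224, 32),
    tumor_window: tuple[int, int, int] = (128, 128, 32),
    localizer_slice_size: int = 256,
    margin: int = 10,
) -> SegmentationResult:
    """Compose localization → liver segmentation → tumor extraction.

    Expects a preprocessed volume; stage errors propagate with their stage
    name attached.
    """
    box = localize_liver(v, models.localizer_2d, margin=margin,
                         slice_size=localizer_slice_size)
    liver_mask, liver_prob = segment_liver(v, box, models.liver_3d,
                                           window_shape=liver_window,
                                           stride_z=max(liver_window[2] // 2, 1))
    tumor_stride = tuple(max(s // 2, 1) for s in tumor_window)
    tumor_mask, tumor_prob = segment_tumor(v, liver_mask, models.tumor_3d,
                                           window_shape=tumor_window,
                                           stride=tumor_stride)
    return SegmentationResult(
        box=box,
        liver_mask=liver_mask,
        tumor_mask=tumor_mask,
        liver_probability=liver_prob,
        tumor_probability=tumor_prob,
    )
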