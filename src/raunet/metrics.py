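"""Volumetric overlap and surface-distance metrics.

Per-case metrics: Dice (DC), Jaccard, volumetric overlap error
(VOE = 1 − Jaccard), signed relative volume difference
(RVD = (|A| − |B|)/|B|, prediction minus reference, so over-segmentation
is positive), average symmetric surface distance (ASSD, mm) and maximum
symmetric surface distance (MSD, symmetric Hausdorff, mm).  The pooled
Dice-global (DG) is the Dice of the voxel counts summed over all cases.

Surfaces are border voxels: the mask minus its single-voxel erosion with a
full 26-neighbourhood; voxels on the volume edge count as surface.
Distances are Euclidean between voxel centers in physical millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DegenerateVolumeError, ShapeError


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask grids differ: {a.shape} vs {b.shape}")
    return a, b


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); both empty → 1, one empty → 0."""
    a, b = _check_pair(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def jaccard_voe_rvd(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(Jaccard, VOE, RVD) with ``b`` the reference mask."""
    a, b = _check_pair(a, b)
    inter = int((a & b).sum())
    union = int((a | b).sum())
    jac = inter / union if union else 1.0
    nb = int(b.sum())
    if nb == 0:
        raise DegenerateVolumeError("RVD is undefined for an empty reference mask")
    rvd = (int(a.sum()) - nb) / nb
    return jac, 1.0 - jac, rvd


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates of border voxels (mask minus its 26-connected erosion)."""
    structure = np.ones((3,) * mask.ndim, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~eroded)


def surface_distances(
    a: np.ndarray, b: np.ndarray, spacing: tuple[float, ...] = (1.0, 1.0, 1.0)
) -> tuple[float, float]:
    """(ASSD, MSD) in millimetres; both masks must be nonempty."""
    a, b = _check_pair(a, b)
    if not a.any() or not b.any():
        raise DegenerateVolumeError("surface distances require two nonempty masks")
    sp = np.asarray(spacing, dtype=float)
    pa = _surface_voxels(a) * sp
    pb = _surface_voxels(b) * sp
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    assd = (d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba))
    msd = max(d_ab.max(), d_ba.max())
    return float(assd), float(msd)


def dice_global(cases: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Dice of the pooled voxel counts: 2Σ|A∩B| / Σ(|A|+|B|)."""
    if not cases:
        raise ValueError("dice_global requires at least one case")
    inter = total = 0
    for a, b in cases:
        a, b = _check_pair(a, b)
        inter += int((a & b).sum())
        total += int(a.sum()) + int(b.sum())
    return 1.0 if total == 0 else 2.0 * inter / total


@dataclass
class MetricsReport:
    """Per-case metric table plus the pooled Dice-global."""

    per_case: pd.DataFrame
    dice_global: float

    def to_csv(self, path) -> None:
        self.per_case.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "per_case": self.per_case.to_dict(orient="records"),
            "pooled": {"dice_global": self.dice_global},
        }
        pd.Series(payload).to_json(path)

    def summary(self) -> dict:
        means = self.per_case.drop(columns=["case_id"]).mean(numeric_only=True)
        out = {k: float(v) for k, v in means.items()}
        out["dice_global"] = self.dice_global
        return out


def evaluate_cases(
    cases: list[tuple[str, np.ndarray, np.ndarray]],
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0),
) -> MetricsReport:
    """Full metric suite for (case_id, prediction, reference) triples.

    Surface distances are reported as NaN when either mask is empty, and
    RVD as NaN for an empty reference, rather than failing the whole report.
    """
    rows = []
    for case_id, pred, ref in cases:
        dc = dice(pred, ref)
        try:
            jac, voe, rvd = jaccard_voe_rvd(pred, ref)
        except DegenerateVolumeError:
            p, r = _check_pair(pred, ref)
            union = int((p | r).sum())
            jac = 1.0 if union == 0 else int((p & r).sum()) / union
            voe, rvd = 1.0 - jac, float("nan")
        try:
            assd, msd = surface_distances(pred, ref, spacing)
        except DegenerateVolumeError:
            assd = msd = float("nan")
        rows.append({"case_id": case_id, "dice": dc, "jaccard": jac,
                     "voe": voe, "rvd": rvd, "assd_mm": assd, "msd_mm": msd})
    dg = dice_global([(p, r) for _, p, r in cases])
    return MetricsReport(per_case=pd.DataFrame(rows), dice_global=dg)
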