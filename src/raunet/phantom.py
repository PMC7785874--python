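"""Synthetic abdominal CT phantoms with exact liver/tumor ground truth.

Each phantom emulates the structure of contrast CT liver studies: an air
background, a partial high-density bone shell, a large ellipsoidal liver
whose voxels sit in the 40–50 HU parenchyma band, and a configurable number
of spherical hypodense lesions (liver HU plus a negative contrast offset)
fully contained in the liver.  Additive Gaussian noise models detector
noise.  Masks are rasterized analytically, so the ground truth is exact by
construction, which makes every downstream contract testable without any
external dataset.

Geometry (ellipsoid liver, spherical tumors) is deliberately idealized:
the generator exists to exercise the pipeline's contracts, not to imitate
anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocessing import Volume, write_volume

LIVER_HU = (40.0, 50.0)  # parenchyma radiodensity band


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and radiodensity parameters of one phantom."""

    seed: int
    shape: tuple[int, int, int] = (160, 160, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.5)
    liver_center: tuple[float, float, float] | None = None  # voxels; None = derived
    liver_semiaxes: tuple[float, float, float] | None = None
    tumor_count: int = 2
    tumor_radius_range: tuple[float, float] = (4.0, 9.0)  # voxels
    tumor_hu_offset: float = -30.0  # hypodense lesions
    background_hu: float = -1000.0  # air
    bone_hu: float = 500.0
    noise_sd: float = 5.0  # HU

    def resolved(self) -> "PhantomConfig":
        nx, ny, nz = self.shape
        center = self.liver_center or (0.45 * nx, 0.50 * ny, 0.50 * nz)
        semi = self.liver_semiaxes or (0.30 * nx, 0.28 * ny, 0.30 * nz)
        if min(semi) <= 0 or min(self.tumor_radius_range) <= 0:
            raise ConfigurationError("semi-axes and tumor radii must be positive")
        return replace(self, liver_center=tuple(center), liver_semiaxes=tuple(semi))


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum((g - c) ** 2 for g, c in zip(grids, center))
    return q <= radius ** 2


def _bone_shell(shape) -> np.ndarray:
    """A partial annular shell in-plane (rib-like arc) over the central z band."""
    nx, ny, nz = shape
    x, y = np.ogrid[0:nx, 0:ny]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    router = 0.48 * min(nx, ny)
    ring = (r >= router - 2.5) & (r <= router)
    angle = np.arctan2(y - cy, x - cx)
    arc = np.cos(angle) > -0.2  # open at the back
    shell = np.zeros(shape, dtype=bool)
    z0, z1 = int(0.15 * nz), int(0.85 * nz)
    shell[:, :, z0:z1] = (ring & arc)[:, :, None]
    return shell


def generate_phantom(cfg: PhantomConfig, return_truth: bool = False):
    """Rasterize one phantom; returns (volume, liver_mask, tumor_mask).

    With ``return_truth=True`` a fourth element is returned: a dict with the
    analytic liver/tumor geometry (centers, semi-axes, radii) actually used,
    for oracle-style verification of the rasterization.
    """
    cfg = cfg.resolved()
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.shape
    liver = _ellipsoid_mask(shape, cfg.liver_center, cfg.liver_semiaxes)
    if not liver.any():
        raise ConfigurationError("liver ellipsoid rasterizes to zero voxels")

    tumor = np.zeros(shape, dtype=bool)
    tumor_truth: list[tuple[tuple[float, float, float], float]] = []
    min_semi = min(cfg.liver_semiaxes)
    for _ in range(cfg.tumor_count):
        radius = rng.uniform(*cfg.tumor_radius_range)
        # conservative containment: the sphere fits if its center lies within
        # the ellipsoid shrunk by radius/min-semiaxis in normalized coords
        max_q = 1.0 - radius / min_semi
        if max_q <= 0:
            raise ConfigurationError(
                f"tumor radius {radius:.1f} cannot fit inside liver semi-axes {cfg.liver_semiaxes}"
            )
        # uniform draw inside the shrunken ellipsoid (normalized coordinates)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        u = direction * max_q * rng.uniform() ** (1.0 / 3.0)
        center = tuple(c + a * ui for c, a, ui in zip(cfg.liver_center, cfg.liver_semiaxes, u))
        tumor |= _sphere_mask(shape, center, radius)
        tumor_truth.append((center, float(radius)))
    tumor &= liver  # exact nesting even at rasterization edges

    hu = np.full(shape, cfg.background_hu, dtype=np.float32)
    hu[_bone_shell(shape)] = cfg.bone_hu
    liver_hu = rng.uniform(LIVER_HU[0], LIVER_HU[1], size=int(liver.sum())).astype(np.float32)
    hu[liver] = liver_hu
    hu[tumor] += cfg.tumor_hu_offset
    if cfg.noise_sd > 0:
        hu += rng.normal(0.0, cfg.noise_sd, size=shape).astype(np.float32)

    affine = np.diag(list(cfg.spacing) + [1.0])
    vol = Volume(hu, spacing=cfg.spacing, affine=affine)
    if return_truth:
        truth = {
            "liver_center": cfg.liver_center,
            "liver_semiaxes": cfg.liver_semiaxes,
            "tumors": tumor_truth,
        }
        return vol, liver, tumor, truth
    return vol, liver, tumor


def labels_from_masks(liver: np.ndarray, tumor: np.ndarray) -> np.ndarray:
    """Combined label volume: 0 background, 1 liver, 2 tumor."""
    labels = np.zeros(liver.shape, dtype=np.uint8)
    labels[liver] = 1
    labels[tumor] = 2
    return labels


def jitter_config(template: PhantomConfig, seed: int) -> PhantomConfig:
    """Deterministically vary the geometry of a template configuration."""
    base = template.resolved()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9e37]))
    center = tuple(c * rng.uniform(0.95, 1.05) for c in base.liver_center)
    semi = tuple(a * rng.uniform(0.90, 1.10) for a in base.liver_semiaxes)
    count = int(rng.integers(max(template.tumor_count - 1, 0), template.tumor_count + 2))
    return replace(base, seed=int(seed), liver_center=center,
                   liver_semiaxes=semi, tumor_count=count)


def generate_cohort(
    n: int,
    template: PhantomConfig,
    seed: int,
    outdir: str | Path | None = None,
) -> tuple[list[tuple[Volume, np.ndarray, np.ndarray]], pd.DataFrame]:
    """Generate `n` phantoms with jittered geometry plus a truth manifest.

    Each case records its own seed in the manifest, so any case can be
    regenerated bitwise-identically via ``jitter_config`` + ``generate_phantom``.
    """
    if n < 1:
        raise ConfigurationError("cohort size must be >= 1")
    master = np.random.default_rng(seed)
    case_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n)]
    cases, rows = [], []
    for i, cseed in enumerate(case_seeds):
        cfg = jitter_config(template, cseed)
        vol, liver, tumor = generate_phantom(cfg)
        cases.append((vol, liver, tumor))
        vox_ml = float(np.prod(cfg.spacing)) / 1000.0
        rows.append({
            "case_id": f"case_{i:03d}",
            "seed": cseed,
            "liver_voxels": int(liver.sum()),
            "liver_volume_ml": liver.sum() * vox_ml,
            "tumor_count": cfg.tumor_count,
            "tumor_voxels": int(tumor.sum()),
            "tumor_volume_ml": tumor.sum() * vox_ml,
        })
        if outdir is not None:
            case_dir = Path(outdir) / rows[-1]["case_id"]
            case_dir.mkdir(parents=True, exist_ok=True)
            write_volume(vol, case_dir / "volume.nii.gz")
            labels = labels_from_masks(liver, tumor)
            write_volume(Volume(labels, vol.spacing, vol.affine), case_dir / "labels.nii.gz")
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        manifest.to_csv(Path(outdir) / "manifest.csv", index=False)
    return cases, manifest
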