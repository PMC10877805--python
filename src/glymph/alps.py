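"""DTI-ALPS index computation.

The ALPS ("analysis along the perivascular space") index probes water
diffusivity along the perivascular spaces that run with the deep medullary
veins at the level of the lateral-ventricle body.  There, projection fibers
run superior-inferior (z) and association fibers anterior-posterior (y),
while the perivascular spaces run left-right (x).  Diffusivity along x in
both fiber regions is therefore attributable to perivascular flow, and the
index is the ratio

    ALPS = (Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc)

of the x-diffusivities to the fiber-perpendicular diffusivities, evaluated
on mean diffusivities inside small spherical ROIs placed in template space.
An index near 1 indicates no preferential perivascular diffusion; healthy
values typically fall between 1.2 and 1.6.

This module evaluates the index on already-fitted diffusivity volumes
(Dxx, Dyy, Dzz) registered to a 2-mm template grid, for a battery of five
anterior-posterior ROI placements (y-shifts of -2..+2 voxels around the
configured centers), left and right, plus the left/right average.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "TensorVolume",
    "RoiSpec",
    "RoiSet",
    "AlpsResult",
    "DEFAULT_ROI_CENTERS",
    "Y_SHIFTS",
    "roi_mask",
    "compute_alps_side",
    "alps_battery",
    "chin_up_excluded",
    "load_roi_config",
]

SIDES = ("left", "right")
FIBER_TYPES = ("projection", "association")

#: Anterior-posterior ROI displacements, in template voxels.
Y_SHIFTS = (-2, -1, 0, 1, 2)

#: Shift used for downstream analyses (the middle ROI placement).
DEFAULT_ANALYSIS_SHIFT = 0

#: Default ROI centers in template mm (RAS).  The template fixes the ROI
#: diameter (6 mm) and space but publishes no coordinates; these defaults
#: sit lateral to the lateral-ventricle body, association fibers lateral to
#: projection fibers, and are overridable via a YAML configuration
#: (:func:`load_roi_config`).
DEFAULT_ROI_CENTERS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("left", "projection"): (-26.0, -6.0, 28.0),
    ("left", "association"): (-36.0, -6.0, 28.0),
    ("right", "projection"): (26.0, -6.0, 28.0),
    ("right", "association"): (36.0, -6.0, 28.0),
}

DEFAULT_ROI_DIAMETER_MM = 6.0


@dataclass
class TensorVolume:
    """Co-registered diffusivity scalar fields on a template grid.

    Diffusivities are in units of 1e-3 mm^2/s.  All three arrays share one
    shape and one voxel-to-mm affine (RAS orientation assumed).
    """

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.dxx = np.asarray(self.dxx, dtype=float)
        self.dyy = np.asarray(self.dyy, dtype=float)
        self.dzz = np.asarray(self.dzz, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if not (self.dxx.shape == self.dyy.shape == self.dzz.shape):
            raise ValueError(
                "dxx/dyy/dzz shapes differ: "
                f"{self.dxx.shape}, {self.dyy.shape}, {self.dzz.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.dxx.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm along the three template axes."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @classmethod
    def from_nifti(cls, dxx_path, dyy_path, dzz_path) -> "TensorVolume":
        imgs = []
        for path in (dxx_path, dyy_path, dzz_path):
            path = Path(path)
            if not path.exists():
                raise FileNotFoundError(f"diffusivity volume not found: {path}")
            imgs.append(nib.load(str(path)))
        ref_affine = imgs[0].affine
        for path, img in zip((dxx_path, dyy_path, dzz_path), imgs):
            if not np.allclose(img.affine, ref_affine, atol=1e-4):
                raise ValueError(f"affine of {path} differs from Dxx affine")
        dxx, dyy, dzz = (np.asarray(i.dataobj, dtype=float) for i in imgs)
        return cls(dxx=dxx, dyy=dyy, dzz=dzz, affine=ref_affine)

    def to_nifti(self, out_dir, prefix: str = "") -> dict[str, Path]:
        """Write the three components as NIfTI files; returns their paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, data in (("dxx", self.dxx), ("dyy", self.dyy), ("dzz", self.dzz)):
            p = out_dir / f"{prefix}{name}.nii.gz"
            nib.Nifti1Image(np.asarray(data, dtype=np.float32), self.affine).to_filename(str(p))
            paths[name] = p
        return paths


@dataclass(frozen=True)
class RoiSpec:
    """A spherical ROI in template space.

    ``y_shift`` displaces the center along the template y-axis (anterior
    positive) by whole voxels of the analysis grid.
    """

    side: str
    fiber_type: str
    center: tuple[float, float, float]
    diameter: float = DEFAULT_ROI_DIAMETER_MM
    y_shift: int = 0

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.fiber_type not in FIBER_TYPES:
            raise ValueError(
                f"fiber_type must be one of {FIBER_TYPES}, got {self.fiber_type!r}"
            )
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")
        if self.y_shift not in Y_SHIFTS:
            raise ValueError(f"y_shift must be in {Y_SHIFTS}, got {self.y_shift}")

    def shifted_center(self, voxel_size_y: float) -> np.ndarray:
        c = np.asarray(self.center, dtype=float).copy()
        c[1] += self.y_shift * voxel_size_y
        return c

    @property
    def label(self) -> str:
        return f"{self.side}-{self.fiber_type} (y_shift={self.y_shift:+d})"


@dataclass
class RoiSet:
    """The four ROI centers (side x fiber type) plus shared diameter."""

    centers: Mapping[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_CENTERS)
    )
    diameter: float = DEFAULT_ROI_DIAMETER_MM

    def __post_init__(self) -> None:
        missing = [k for k in DEFAULT_ROI_CENTERS if k not in self.centers]
        if missing:
            raise ValueError(f"RoiSet missing centers for {missing}")

    def spec(self, side: str, fiber_type: str, y_shift: int = 0) -> RoiSpec:
        return RoiSpec(
            side=side,
            fiber_type=fiber_type,
            center=tuple(self.centers[(side, fiber_type)]),
            diameter=self.diameter,
            y_shift=y_shift,
        )


@dataclass
class AlpsResult:
    """Per-shift left/right/average indices plus an audit of ROI means."""

    left: dict[int, float]
    right: dict[int, float]
    average: dict[int, float]
    roi_means: dict[str, dict[str, float]]
    qc_flags: list[str]

    def index(self, shift: int = DEFAULT_ANALYSIS_SHIFT, side: str = "average") -> float:
        table = {"left": self.left, "right": self.right, "average": self.average}[side]
        return table[shift]

    def to_row(self) -> dict[str, float]:
        """Flatten to one table row: 5 shifts x {L, R, mean}."""
        row: dict[str, float] = {}
        for shift in Y_SHIFTS:
            row[f"alps_left_shift{shift:+d}"] = self.left[shift]
            row[f"alps_right_shift{shift:+d}"] = self.right[shift]
            row[f"alps_mean_shift{shift:+d}"] = self.average[shift]
        return row

    def audit_json(self) -> str:
        return json.dumps(
            {"roi_means": self.roi_means, "qc_flags": self.qc_flags}, indent=2, sort_keys=True
        )


def roi_mask(spec: RoiSpec, vol: TensorVolume) -> np.ndarray:
    """Boolean voxel mask of the (possibly y-shifted) ROI sphere.

    A voxel belongs to the ROI iff its center lies within ``diameter / 2``
    of the sphere center.  Raises if the sphere misses every voxel center.
    """
    voxel_size = vol.voxel_size
    center = spec.shifted_center(voxel_size[1])
    radius = spec.diameter / 2.0

    inv = np.linalg.inv(vol.affine)
    center_vox = (inv @ np.append(center, 1.0))[:3]
    # Restrict to the bounding box of the sphere before the exact test.
    lo = np.maximum(np.floor(center_vox - radius / voxel_size - 1).astype(int), 0)
    hi = np.minimum(
        np.ceil(center_vox + radius / voxel_size + 1).astype(int) + 1,
        np.asarray(vol.shape),
    )
    mask = np.zeros(vol.shape, dtype=bool)
    if np.any(lo >= hi):
        raise ValueError(f"ROI {spec.label} lies outside the volume grid")
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    mm = vox @ vol.affine.T
    dist2 = ((mm[..., :3] - center) ** 2).sum(axis=-1)
    inside = dist2 <= radius**2 + 1e-9
    mask[ii[inside], jj[inside], kk[inside]] = True
    if not mask.any():
        raise ValueError(f"ROI {spec.label} contains no voxel centers")
    return mask


def compute_alps_side(
    dxx_proj: float, dxx_assoc: float, dyy_proj: float, dzz_assoc: float
) -> float:
    """One-hemisphere index: (Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc)."""
    for name, v in (
        ("dxx_proj", dxx_proj),
        ("dxx_assoc", dxx_assoc),
        ("dyy_proj", dyy_proj),
        ("dzz_assoc", dzz_assoc),
    ):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {v}")
    denom = dyy_proj + dzz_assoc
    if denom <= 0:
        raise ValueError(
            "degenerate ROI content: Dyy_proj + Dzz_assoc must be positive, "
            f"got {denom}"
        )
    return (dxx_proj + dxx_assoc) / denom


def alps_battery(vol: TensorVolume, rois: RoiSet | None = None) -> AlpsResult:
    """Evaluate the index for all five y-shifts, both sides, and the average.

    The result also retains the four ROI mean diffusivities per side/shift
    for audit, and QC flags for implausible content (non-positive mean
    diffusivity, index outside [0.5, 3.0]).
    """
    rois = rois or RoiSet()
    left: dict[int, float] = {}
    right: dict[int, float] = {}
    average: dict[int, float] = {}
    roi_means: dict[str, dict[str, float]] = {}
    qc_flags: list[str] = []

    for shift in Y_SHIFTS:
        per_side: dict[str, float] = {}
        for side in SIDES:
            means: dict[str, float] = {}
            for fiber in FIBER_TYPES:
                spec = rois.spec(side, fiber, y_shift=shift)
                try:
                    mask = roi_mask(spec, vol)
                except ValueError as exc:
                    raise ValueError(f"ROI {spec.label}: {exc}") from exc
                means[f"dxx_{fiber}"] = float(vol.dxx[mask].mean())
                means[f"dyy_{fiber}"] = float(vol.dyy[mask].mean())
                means[f"dzz_{fiber}"] = float(vol.dzz[mask].mean())
            key = f"{side}_shift{shift:+d}"
            roi_means[key] = means
            if min(means.values()) <= 0:
                qc_flags.append(f"nonpositive_diffusivity:{key}")
            try:
                idx = compute_alps_side(
                    means["dxx_projection"],
                    means["dxx_association"],
                    means["dyy_projection"],
                    means["dzz_association"],
                )
            except ValueError as exc:
                raise ValueError(f"{side} side, shift {shift:+d}: {exc}") from exc
            if not 0.5 <= idx <= 3.0:
                qc_flags.append(f"implausible_index:{key}")
            per_side[side] = idx
        left[shift] = per_side["left"]
        right[shift] = per_side["right"]
        average[shift] = (per_side["left"] + per_side["right"]) / 2.0

    return AlpsResult(
        left=left, right=right, average=average, roi_means=roi_means, qc_flags=qc_flags
    )


def chin_up_excluded(acpc_angle_deg: float) -> bool:
    """True iff the AC-PC line is tilted more than 20 degrees above horizontal.

    The index is sensitive to head pitch; scans acquired with a chin-up
    position beyond 20 degrees are excluded (strictly greater than).
    """
    if not math.isfinite(acpc_angle_deg):
        raise ValueError("AC-PC angle must be finite")
    return acpc_angle_deg > 20.0


def load_roi_config(path) -> RoiSet:
    """Read ROI centers/diameter from YAML.

    Expected layout::

        diameter: 6.0
        centers:
          left:
            projection: [-26.0, -6.0, 28.0]
            association: [-36.0, -6.0, 28.0]
          right:
            projection: [26.0, -6.0, 28.0]
            association: [36.0, -6.0, 28.0]
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    centers = {
        (side, fiber): tuple(float(v) for v in coords)
        for side, fibers in cfg["centers"].items()
        for fiber, coords in fibers.items()
    }
    return RoiSet(centers=centers, diameter=float(cfg.get("diameter", DEFAULT_ROI_DIAMETER_MM)))
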