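"""Tensor phantoms with a known ground-truth ALPS index.

The phantom places axis-aligned rectangular slabs of anisotropic
diffusivity around the projection- and association-fiber ROI positions on
a 2-mm template grid, embedded in an isotropic background.  Inside the
projection slabs the perpendicular component is Dyy, inside the
association slabs it is Dzz; the x-components are set to
``alps_truth * d_perp`` in both, so the index

    (Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc)

evaluates exactly to ``alps_truth`` in the noiseless case, for any ROI
fully contained in its slab (slabs are homogeneous, so every y-shifted ROI
placement sees the same means).  Optional i.i.d. Gaussian noise on all
three components emulates estimation noise in the fitted tensors.

Axis-aligned slabs stand in for curved fiber tracts deliberately: the
index only reads mean diffusivities inside spherical ROIs, so slab
geometry is sufficient and keeps the ground truth analytic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alps import DEFAULT_ROI_CENTERS, DEFAULT_ROI_DIAMETER_MM, Y_SHIFTS, TensorVolume

__all__ = ["PhantomSpec", "generate_tensor_phantom", "write_phantom"]

#: Template affine for the default 2-mm phantom grid (RAS, voxel centers on
#: even-mm coordinates so the default ROI centers coincide with voxel centers).
_DEFAULT_SHAPE = (64, 64, 40)
_DEFAULT_OFFSET = (-64.0, -40.0, -20.0)


def _default_affine(voxel_size: float, offset) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    aff[:3, 3] = offset
    return aff


def _default_slabs() -> dict[tuple[str, str], tuple[tuple[float, float, float], tuple[float, float, float]]]:
    """Slab boxes as (center_mm, half_extent_mm) around each default ROI."""
    half = (5.0, 9.0, 5.0)  # covers a 3-mm ROI radius plus +-2-voxel y-shifts
    return {key: (center, half) for key, center in DEFAULT_ROI_CENTERS.items()}


@dataclass
class PhantomSpec:
    """Configuration of a ground-truth tensor phantom.

    Parameters
    ----------
    alps_truth
        The dimensionless index value the noiseless phantom must produce.
    d_perp
        Perpendicular diffusivity inside the fiber slabs (1e-3 mm^2/s).
    d_axial
        Diffusivity along each slab's fiber axis (not read by the index).
    d_background
        Isotropic diffusivity outside the slabs.
    noise_sd
        SD of additive Gaussian noise applied to all three components.
    """

    alps_truth: float = 1.355
    d_perp: float = 0.7
    d_axial: float = 1.4
    d_background: float = 0.8
    shape: tuple[int, int, int] = _DEFAULT_SHAPE
    voxel_size: float = 2.0
    offset: tuple[float, float, float] = _DEFAULT_OFFSET
    slabs: dict = field(default_factory=_default_slabs)
    roi_diameter: float = DEFAULT_ROI_DIAMETER_MM
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alps_truth > 0:
            raise ValueError("alps_truth must be positive")
        if not self.d_perp > 0:
            raise ValueError("d_perp must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self._validate_slabs()

    @property
    def affine(self) -> np.ndarray:
        return _default_affine(self.voxel_size, self.offset)

    def _validate_slabs(self) -> None:
        """Each slab must contain its ROI sphere for every y-shift, and lie
        inside the grid."""
        radius = self.roi_diameter / 2.0
        shift_mm = max(abs(s) for s in Y_SHIFTS) * self.voxel_size
        lo_grid = np.asarray(self.offset) - self.voxel_size / 2.0
        hi_grid = lo_grid + np.asarray(self.shape) * self.voxel_size
        for key, (center, half) in self.slabs.items():
            center = np.asarray(center, dtype=float)
            half = np.asarray(half, dtype=float)
            need = np.array([radius, radius + shift_mm, radius])
            if np.any(half < need):
                raise ValueError(
                    f"slab for ROI {key} (half-extent {tuple(half)}) is smaller than "
                    f"the shifted ROI sphere (needs >= {tuple(need)})"
                )
            if np.any(center - half < lo_grid) or np.any(center + half > hi_grid):
                raise ValueError(f"slab for ROI {key} extends outside the phantom grid")


def generate_tensor_phantom(spec: PhantomSpec) -> tuple[TensorVolume, dict]:
    """Build the phantom volume and its ground-truth record.

    Returns the :class:`TensorVolume` plus a dict with the exact noiseless
    index per hemisphere and the generating parameters.
    """
    affine = spec.affine
    dxx = np.full(spec.shape, spec.d_background, dtype=float)
    dyy = dxx.copy()
    dzz = dxx.copy()

    # Voxel-center coordinates in mm.
    idx = np.indices(spec.shape, dtype=float)
    coords = [idx[a] * spec.voxel_size + spec.offset[a] for a in range(3)]

    d_along_x = spec.alps_truth * spec.d_perp
    for (side, fiber), (center, half) in spec.slabs.items():
        center = np.asarray(center, dtype=float)
        half = np.asarray(half, dtype=float)
        inside = np.ones(spec.shape, dtype=bool)
        for a in range(3):
            inside &= np.abs(coords[a] - center[a]) <= half[a] + 1e-9
        dxx[inside] = d_along_x
        if fiber == "projection":
            # fibers along z: y is perpendicular, z axial
            dyy[inside] = spec.d_perp
            dzz[inside] = spec.d_axial
        else:
            # association fibers along y: z perpendicular, y axial
            dzz[inside] = spec.d_perp
            dyy[inside] = spec.d_axial

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        dxx = dxx + rng.normal(0.0, spec.noise_sd, spec.shape)
        dyy = dyy + rng.normal(0.0, spec.noise_sd, spec.shape)
        dzz = dzz + rng.normal(0.0, spec.noise_sd, spec.shape)

    truth = {
        "alps_truth": spec.alps_truth,
        "left": spec.alps_truth,
        "right": spec.alps_truth,
        "average": spec.alps_truth,
        "d_perp": spec.d_perp,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return TensorVolume(dxx=dxx, dyy=dyy, dzz=dzz, affine=affine), truth


def write_phantom(spec: PhantomSpec, out_dir, prefix: str = "") -> dict[str, Path]:
    """Write Dxx/Dyy/Dzz NIfTI files plus a JSON ground-truth sidecar."""
    vol, truth = generate_tensor_phantom(spec)
    paths = vol.to_nifti(out_dir, prefix=prefix)
    sidecar = Path(out_dir) / f"{prefix}ground_truth.json"
    sidecar.write_text(json.dumps(truth, indent=2, sort_keys=True))
    paths["ground_truth"] = sidecar
    return paths
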