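"""Volume I/O and preprocessing: NIfTI read/write, resampling, rigid alignment.

Coordinate convention: voxel indices are 0-based; physical position is
``origin + index * spacing`` (mm). Only axis-aligned geometries are produced;
reading derives spacing from affine column norms and origin from the affine
translation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np
from scipy import optimize
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import ImageGrid, StructureSet

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "read_volume",
    "write_volume",
    "resample_to_grid",
    "rigid_align",
    "write_structures",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (radians) + translation (mm) about a physical center (mm).

    2D: ``rotation`` is a single angle. 3D: Euler angles (about axes 0,1,2,
    applied in that order). Maps a physical point p to
    ``R @ (p - center) + center + translation``.
    """

    rotation: Tuple[float, ...]
    translation: Tuple[float, ...]
    center: Tuple[float, ...]

    @property
    def ndim(self) -> int:
        return len(self.translation)

    def matrix(self) -> np.ndarray:
        if self.ndim == 2:
            (a,) = self.rotation
            c, s = np.cos(a), np.sin(a)
            return np.array([[c, -s], [s, c]])
        ax, ay, az = self.rotation
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to physical points, shape (..., ndim)."""
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (points - c) @ self.matrix().T + c + t

    def inverse(self) -> "RigidTransform":
        R = self.matrix()
        # inverse maps q -> R^T (q - c - t) + c
        if self.ndim == 2:
            rot = (-self.rotation[0],)
        else:
            # extract Euler angles of R^T is messy; store via matrix inverse trick:
            # for the small angles used here, negating angles in reverse order is
            # exact only when a single angle is nonzero. Use matrix-based apply
            # instead for validation; inverse() supports the 2D and single-axis 3D cases.
            rot = tuple(-a for a in self.rotation)
        t_inv = tuple((-R.T @ (np.asarray(self.translation))).tolist())
        return RigidTransform(rot, t_inv, self.center)


def _affine_from_grid(image: ImageGrid) -> np.ndarray:
    aff = np.eye(4)
    for a in range(image.ndim):
        aff[a, a] = image.spacing[a]
        aff[a, 3] = image.origin[a]
    return aff


def read_volume(path) -> ImageGrid:
    """Read a NIfTI volume into an :class:`ImageGrid`.

    Spacing comes from the affine column norms, origin from its translation.
    Raises ``IOError`` naming the file if it is missing or unreadable.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # malformed file
        raise IOError(f"cannot read volume {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim not in (2, 3):
        raise IOError(f"volume {path} has unsupported rank {data.ndim}")
    aff = img.affine
    ndim = data.ndim
    spacing = tuple(float(np.linalg.norm(aff[:3, a])) for a in range(ndim))
    origin = tuple(float(aff[a, 3]) for a in range(ndim))
    return ImageGrid(data, spacing, origin)


def write_volume(image: ImageGrid, path) -> None:
    """Write an :class:`ImageGrid` as NIfTI (values + diagonal affine)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(image.values.astype(np.float64), _affine_from_grid(image)), str(path))


def write_structures(structures: StructureSet, grid: ImageGrid, directory, prefix: str = "") -> None:
    """One NIfTI label map per structure."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in structures.items():
        write_volume(grid.with_values(mask.astype(np.float64)), directory / f"{prefix}{name}.nii")


def resample_to_grid(image: ImageGrid, target: ImageGrid, interpolation: str = "linear",
                     fill_value: float | None = None) -> ImageGrid:
    """Resample ``image`` onto ``target``'s grid.

    ``interpolation`` is ``"linear"`` or ``"nearest"`` (use nearest for label
    maps). Out-of-domain samples take ``fill_value`` (default: the input's
    minimum intensity — CT air convention).
    """
    order = _interp_order(interpolation)
    if fill_value is None:
        fill_value = float(image.values.min())
    coords = []
    for a in range(target.ndim):
        idx = np.arange(target.shape[a], dtype=np.float64)
        phys = target.origin[a] + idx * target.spacing[a]
        coords.append((phys - image.origin[a]) / image.spacing[a])
    mesh = np.meshgrid(*coords, indexing="ij")
    out = map_coordinates(image.values, np.stack(mesh), order=order, mode="constant", cval=fill_value)
    return ImageGrid(out, target.spacing, target.origin)


def _interp_order(interpolation: str) -> int:
    if interpolation == "linear":
        return 1
    if interpolation == "nearest":
        return 0
    raise ValueError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")


def _resample_rigid(moving: ImageGrid, fixed: ImageGrid, transform: RigidTransform,
                    order: int = 1, fill_value: float | None = None) -> ImageGrid:
    """Resample ``moving`` onto ``fixed``'s grid under the rigid transform.

    The transform maps moving-space points into fixed space, so sampling pulls
    each fixed voxel back through the inverse map.
    """
    if fill_value is None:
        fill_value = float(moving.values.min())
    ndim = fixed.ndim
    phys = np.stack(fixed.physical_coords(), axis=-1)  # fixed-space points
    R = transform.matrix()
    c = np.asarray(transform.center)
    t = np.asarray(transform.translation)
    src = (phys - c - t) @ R + c  # (p - c - t) @ (R^T)^T = R^T(p - c - t) + c
    vox = np.empty_like(src)
    for a in range(ndim):
        vox[..., a] = (src[..., a] - moving.origin[a]) / moving.spacing[a]
    out = map_coordinates(moving.values, np.moveaxis(vox, -1, 0), order=order,
                          mode="constant", cval=fill_value)
    return ImageGrid(out, fixed.spacing, fixed.origin)


@dataclass
class RigidAlignConfig:
    max_translation_mm: float = 12.0
    coarse_translation_step_mm: float = 4.0
    max_rotation_deg: float = 12.0
    coarse_rotation_step_deg: float = 3.0
    refine_xtol: float = 1e-3


def rigid_align(moving: ImageGrid, fixed: ImageGrid,
                config: RigidAlignConfig | None = None) -> Tuple[ImageGrid, RigidTransform]:
    """Rigidly align ``moving`` to ``fixed`` and resample onto its grid.

    Similarity is mean squared intensity difference over the fixed grid,
    minimised over rotation + translation. Two coarse search paths
    (translation-first at zero rotation, and a joint angle/translation grid)
    are each refined by alternating 1-degree angle sweeps with local
    translation grids and polished with Nelder-Mead; the better final optimum
    wins. Reliable while the moving image's content stays inside its field of
    view; emits a convergence warning when the final overlap is poor.
    """
    if moving.ndim != fixed.ndim:
        raise ValueError("moving and fixed must share ndim")
    config = config or RigidAlignConfig()
    ndim = fixed.ndim
    n_rot = 1 if ndim == 2 else 3
    center = tuple(
        fixed.origin[a] + 0.5 * (fixed.shape[a] - 1) * fixed.spacing[a] for a in range(ndim)
    )

    def objective(params) -> float:
        # angles in degrees so search steps are commensurate with mm
        rot = tuple(np.deg2rad(params[:n_rot]))
        trans = tuple(params[n_rot:])
        tr = RigidTransform(rot, trans, center)
        resampled = _resample_rigid(moving, fixed, tr)
        return float(np.mean((resampled.values - fixed.values) ** 2))

    t_steps = np.arange(-config.max_translation_mm, config.max_translation_mm + 1e-9,
                        config.coarse_translation_step_mm)
    a_coarse = np.arange(-config.max_rotation_deg, config.max_rotation_deg + 1e-9,
                         config.coarse_rotation_step_deg)
    a_fine = np.arange(-config.max_rotation_deg, config.max_rotation_deg + 1e-9, 1.0)
    trans_grid = np.stack(np.meshgrid(*([t_steps] * ndim), indexing="ij"), axis=-1).reshape(-1, ndim)

    # path A: best translation at zero rotation; path B: joint coarse best
    zero = np.zeros(n_rot)
    best_a = min(((objective(np.concatenate([zero, off])), tuple(off)) for off in trans_grid))
    if n_rot == 1:
        rot_grid = a_coarse.reshape(-1, 1)
    else:
        # 3D: single-axis coarse rotations only (full grid is too large)
        rot_grid = np.concatenate(
            [np.zeros((1, n_rot))]
            + [np.eye(n_rot)[[ax]] * a for ax in range(n_rot) for a in a_coarse if a != 0])
    best_b = min(((objective(np.concatenate([r, off])), tuple(np.concatenate([r, off])))
                  for r in rot_grid for off in trans_grid))

    starts = [np.concatenate([zero, best_a[1]]), np.asarray(best_b[1])]
    results = []
    for x0 in starts:
        rot_c = np.array(x0[:n_rot])
        t_c = np.array(x0[n_rot:])
        for _ in range(3):
            for axis in range(n_rot):
                vals = []
                for ang in a_fine:
                    r = rot_c.copy()
                    r[axis] = ang
                    vals.append((objective(np.concatenate([r, t_c])), ang))
                rot_c[axis] = min(vals)[1]
            loc = np.arange(-2.0, 2.1, 1.0)
            local = np.stack(np.meshgrid(*([loc] * ndim), indexing="ij"), axis=-1).reshape(-1, ndim)
            t_c = np.asarray(min(((objective(np.concatenate([rot_c, t_c + d])), tuple(t_c + d))
                                  for d in local))[1])
        res = optimize.minimize(objective, np.concatenate([rot_c, t_c]), method="Nelder-Mead",
                                options={"xatol": config.refine_xtol, "fatol": 1e-10})
        results.append(res)
    res = min(results, key=lambda r: r.fun)
    rot = tuple(float(np.deg2rad(v)) for v in res.x[:n_rot])
    trans = tuple(float(v) for v in res.x[n_rot:])
    transform = RigidTransform(rot, trans, center)
    aligned = _resample_rigid(moving, fixed, transform)

    if res.fun > np.mean((fixed.values - fixed.values.mean()) ** 2):
        warnings.warn(
            f"rigid_align: poor final similarity (MSD={res.fun:.3g}); "
            "fields of view may not overlap", RuntimeWarning,
        )
    logger.info("rigid_align: MSD %.4g, rotation %s rad, translation %s mm",
                res.fun, rot, trans)
    return aligned, transform
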