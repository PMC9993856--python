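"""Log-domain diffeomorphic demons registration.

The transform is maintained as the exponential of a stationary velocity field
V. Each iteration computes a demons force from the current warped image,
caps and fluid-smooths it, accumulates it into V (first-order log-domain
composition V <- V + v), diffusion-smooths V, and re-exponentiates via
scaling-and-squaring. Multiresolution runs coarse to fine.

All fields are in millimetres on the physical axes; sampling during warping
and composition is spacing-aware with clamp-to-edge boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter, map_coordinates, zoom as nd_zoom

from .core import DisplacementField, ImageGrid, VelocityField
from .phantom import jacobian_determinant

logger = logging.getLogger(__name__)

__all__ = [
    "DemonsConfig",
    "demons_energy",
    "exp_velocity",
    "compose_displacements",
    "demons_update",
    "register_diffeodemons",
    "warp_image",
    "warp_structures",
]


@dataclass
class DemonsConfig:
    regularization_weight: float = 1.0     # lambda in the energy (diagnostic; smoothing regularises)
    sigma_fluid_mm: float = 2.0
    sigma_diffusion_mm: float = 1.0
    iterations_per_level: int = 50
    levels: int = 3
    squaring_steps: int = 6
    step_bound_mm: float = 2.0
    energy_tolerance: float = 1e-6         # relative energy change stopping rule
    reject_worsening: bool = False         # keep the energy trace strictly non-increasing
    intensity_scale: float = 1000.0        # demons normalisation scale (HU-like data)

    def __post_init__(self):
        if self.regularization_weight < 0:
            raise ValueError("regularization_weight must be >= 0")
        if self.sigma_fluid_mm < 0 or self.sigma_diffusion_mm < 0:
            raise ValueError("smoothing widths must be >= 0")
        if self.iterations_per_level < 1 or self.levels < 1:
            raise ValueError("iterations and levels must be >= 1")
        if self.squaring_steps < 0:
            raise ValueError("squaring_steps must be >= 0")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DemonsConfig":
        return cls(**yaml.safe_load(text))


def _sample_vectors(vec: np.ndarray, coords_vox: np.ndarray) -> np.ndarray:
    """Linear-sample a vector field (grid + (ndim,)) at voxel coordinates."""
    out = np.empty(coords_vox.shape[1:] + (vec.shape[-1],))
    for c in range(vec.shape[-1]):
        out[..., c] = map_coordinates(vec[..., c], coords_vox, order=1, mode="nearest")
    return out


def warp_image(image: ImageGrid, dvf: DisplacementField, interpolation: str = "linear") -> ImageGrid:
    """Pull-back warp: output(x) = input(x + u(x)), spacing-aware.

    Use ``"nearest"`` for label maps (keeps values binary).
    """
    if image.shape != dvf.grid_shape:
        raise ValueError(f"grid mismatch: image {image.shape} vs dvf {dvf.grid_shape}")
    if interpolation == "linear":
        order = 1
    elif interpolation == "nearest":
        order = 0
    else:
        raise ValueError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    ndim = image.ndim
    idx = np.stack(image.index_coords())
    coords = np.empty_like(idx)
    for a in range(ndim):
        coords[a] = idx[a] + dvf.vectors[..., a] / image.spacing[a]
    out = map_coordinates(image.values, coords, order=order, mode="nearest")
    return image.with_values(out)


def warp_structures(structures, dvf: DisplacementField):
    """Nearest-neighbour warp of every mask in a StructureSet."""
    from .core import StructureSet

    out = {}
    for name, mask in structures.items():
        g = ImageGrid(mask.astype(np.float64), dvf.spacing, dvf.origin)
        out[name] = warp_image(g, dvf, "nearest").values.astype(np.uint8)
    return StructureSet(out)


def compose_displacements(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Displacement of (Id + outer) o (Id + inner): u(x) = inner(x) + outer(x + inner(x))."""
    if outer.grid_shape != inner.grid_shape:
        raise ValueError("grid mismatch in composition")
    ndim = outer.ndim
    idx = np.stack([np.meshgrid(*[np.arange(n, dtype=np.float64) for n in outer.grid_shape],
                                indexing="ij")[a] for a in range(ndim)])
    coords = np.empty_like(idx)
    for a in range(ndim):
        coords[a] = idx[a] + inner.vectors[..., a] / outer.spacing[a]
    outer_at = _sample_vectors(outer.vectors, coords)
    return DisplacementField(inner.vectors + outer_at, outer.spacing, outer.origin)


def exp_velocity(v: VelocityField, squaring_steps: int = 6) -> DisplacementField:
    """Exponential of a stationary velocity field by scaling and squaring.

    Scale v by 2**(-k), treat the result as a small displacement, then
    self-compose k times. squaring_steps = 0 returns v itself as a
    displacement (one Euler step).
    """
    if squaring_steps < 0:
        raise ValueError("squaring_steps must be >= 0")
    u = DisplacementField(v.vectors / (2.0 ** squaring_steps), v.spacing, v.origin)
    for _ in range(squaring_steps):
        u = compose_displacements(u, u)
    return u


def _spatial_gradient(values: np.ndarray, spacing) -> np.ndarray:
    return np.stack([np.gradient(values, spacing[a], axis=a) for a in range(values.ndim)], axis=-1)


def demons_energy(moving: ImageGrid, fixed: ImageGrid, displacement: DisplacementField,
                  regularization_weight: float = 1.0) -> float:
    """SSD(moving o phi, fixed) + lambda * ||grad u||^2.

    The smoothness penalty is taken on the displacement u = phi - Id
    (spacing-aware finite differences) so the identity transform scores zero
    regularisation.
    """
    if moving.shape != fixed.shape or moving.shape != displacement.grid_shape:
        raise ValueError("moving, fixed and displacement must share one grid")
    warped = warp_image(moving, displacement, "linear")
    ssd = float(np.sum((warped.values - fixed.values) ** 2))
    reg = 0.0
    for c in range(displacement.ndim):
        g = _spatial_gradient(displacement.vectors[..., c], displacement.spacing)
        reg += float(np.sum(g**2))
    return ssd + regularization_weight * reg


def demons_update(moving: ImageGrid, fixed: ImageGrid, current: DisplacementField,
                  config: DemonsConfig) -> VelocityField:
    """One demons force: cap to the step bound, then fluid-smooth.

    Force at each voxel is ``-(Im o phi - If) * grad(Im o phi) /
    (|grad|^2 + (diff/scale)^2)`` — the classical demons normalisation with
    the intensity difference scaled to keep units of mm.
    """
    if moving.shape != fixed.shape:
        raise ValueError("grid mismatch")
    warped = warp_image(moving, current, "linear")
    diff = warped.values - fixed.values
    grad = _spatial_gradient(warped.values, moving.spacing)
    grad_sq = np.sum(grad**2, axis=-1)
    scale = max(config.intensity_scale, 1e-12)
    denom = grad_sq + diff**2 / scale
    force = np.where(
        (denom > 1e-12)[..., None],
        -diff[..., None] * grad / np.maximum(denom, 1e-12)[..., None],
        0.0,
    )
    # cap magnitude at the step bound
    mag = np.sqrt(np.sum(force**2, axis=-1))
    over = mag > config.step_bound_mm
    if np.any(over):
        force[over] *= (config.step_bound_mm / mag[over])[..., None]
    if config.sigma_fluid_mm > 0:
        for c in range(force.shape[-1]):
            force[..., c] = gaussian_filter(
                force[..., c], [config.sigma_fluid_mm / s for s in moving.spacing]
            )
    return VelocityField(force, moving.spacing, moving.origin)


def _zero_boundary(vec: np.ndarray) -> None:
    for a in range(vec.ndim - 1):
        sl = [slice(None)] * (vec.ndim - 1)
        sl[a] = 0
        vec[tuple(sl)] = 0.0
        sl[a] = -1
        vec[tuple(sl)] = 0.0


def _downsample(image: ImageGrid, factor: int) -> ImageGrid:
    if factor == 1:
        return image
    blurred = gaussian_filter(image.values, factor / 2.0)
    new_shape = tuple(max(8, n // factor) for n in image.shape)
    zoom = [ns / n for ns, n in zip(new_shape, image.shape)]
    data = nd_zoom(blurred, zoom, order=1, mode="nearest")
    spacing = tuple(image.spacing[a] * image.shape[a] / data.shape[a] for a in range(image.ndim))
    return ImageGrid(data, spacing, image.origin)


def _upsample_velocity(v: VelocityField, target_shape, target_spacing, origin) -> VelocityField:
    zoom = [ts / s for ts, s in zip(target_shape, v.grid_shape)]
    out = np.stack(
        [nd_zoom(v.vectors[..., c], zoom, order=1, mode="nearest") for c in range(v.ndim)],
        axis=-1,
    )
    return VelocityField(out, target_spacing, origin)


def register_diffeodemons(fixed: ImageGrid, moving: ImageGrid,
                          config: DemonsConfig | None = None
                          ) -> Tuple[DisplacementField, Dict]:
    """Estimate the DVF warping ``moving`` onto ``fixed``.

    Returns the displacement field u (so moving(x + u(x)) ~ fixed(x)) and a
    diagnostics dict with the per-iteration energy trace per level, the final
    energy and the minimum Jacobian determinant.
    """
    if not fixed.same_geometry(moving):
        raise ValueError("fixed and moving must share a grid (preprocess first)")
    config = config or DemonsConfig()

    factors = [2 ** (config.levels - 1 - i) for i in range(config.levels)]
    v: VelocityField | None = None
    traces: List[List[float]] = []
    for level, factor in enumerate(factors):
        f_lvl = _downsample(fixed, factor)
        m_lvl = _downsample(moving, factor)
        if v is None:
            v = VelocityField.zeros(f_lvl.shape, f_lvl.spacing, f_lvl.origin)
        else:
            v = _upsample_velocity(v, f_lvl.shape, f_lvl.spacing, f_lvl.origin)
        trace: List[float] = []
        u = exp_velocity(v, config.squaring_steps)
        energy = demons_energy(m_lvl, f_lvl, u, config.regularization_weight)
        if not np.isfinite(energy):
            raise FloatingPointError("non-finite registration energy at start")
        trace.append(energy)
        for it in range(config.iterations_per_level):
            dv = demons_update(m_lvl, f_lvl, u, config)
            new_vec = v.vectors + dv.vectors
            if config.sigma_diffusion_mm > 0:
                for c in range(new_vec.shape[-1]):
                    new_vec[..., c] = gaussian_filter(
                        new_vec[..., c], [config.sigma_diffusion_mm / s for s in f_lvl.spacing]
                    )
            _zero_boundary(new_vec)
            v_new = VelocityField(new_vec, f_lvl.spacing, f_lvl.origin)
            u_new = exp_velocity(v_new, config.squaring_steps)
            e_new = demons_energy(m_lvl, f_lvl, u_new, config.regularization_weight)
            if not np.isfinite(e_new):
                raise FloatingPointError(f"non-finite energy at level {level} iter {it}")
            if config.reject_worsening and e_new > trace[-1]:
                break
            v, u = v_new, u_new
            rel = abs(trace[-1] - e_new) / max(trace[-1], 1e-12)
            trace.append(e_new)
            if rel < config.energy_tolerance:
                break
        traces.append(trace)
        logger.info("demons level %d (factor %d): energy %.4g -> %.4g in %d iters",
                    level, factor, trace[0], trace[-1], len(trace) - 1)

    u = exp_velocity(v, config.squaring_steps)
    # resample to the native grid if the coarsest level padded shapes
    if u.grid_shape != fixed.shape:
        v = _upsample_velocity(v, fixed.shape, fixed.spacing, fixed.origin)
        u = exp_velocity(v, config.squaring_steps)
    min_jac = float(jacobian_determinant(u).min())
    diagnostics = {
        "energy_traces": traces,
        "final_energy": traces[-1][-1],
        "min_jacobian": min_jac,
        "config": asdict(config),
    }
    return DisplacementField(u.vectors, fixed.spacing, fixed.origin), diagnostics
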