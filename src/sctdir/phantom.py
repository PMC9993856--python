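"""Synthetic phantom generation.

Produces paired data for end-to-end experiments: a clean planning-CT-like
volume with nested target structures (body, heart, CTV2, CTV1), a smooth
random ground-truth deformation standing in for inter-fraction anatomical
change, and an artifact-degraded CBCT-like counterpart (contrast compression,
low-frequency shading, sparse streaks, noise).

Phantoms are 2D by default; :func:`stack_slices` builds a 3D volume from
repeated 2D slices. Intensities are on an HU-like scale (air -1000, soft
tissue ~0-100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .core import ImageGrid, StructureSet, DisplacementField

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomConfig",
    "ArtifactConfig",
    "generate_phantom",
    "sample_smooth_deformation",
    "degrade_to_cbct",
    "stack_slices",
    "jacobian_determinant",
]


@dataclass
class PhantomConfig:
    """Geometry and intensity model for a 2D (or 3D) torso-slice phantom.

    Centers and radii are in millimetres, measured from the image origin.
    Structure radii must nest: CTV1 inside CTV2 inside body.
    """

    shape: Tuple[int, ...] = (128, 128)
    spacing: Tuple[float, ...] = (1.0, 1.0)
    body_center: Optional[Tuple[float, ...]] = None   # default: image centre
    body_radii: Optional[Tuple[float, ...]] = None    # default: 45% of extent
    heart_center_offset: Tuple[float, ...] = (-8.0, -18.0)  # mm from body centre
    heart_radius: float = 15.0
    ctv2_center_offset: Tuple[float, ...] = (2.0, 22.0)
    ctv2_radius: float = 18.0
    ctv1_center_offset: Tuple[float, ...] = (4.0, 24.0)
    ctv1_radius: float = 8.0
    air_hu: float = -1000.0
    body_hu: float = 40.0
    heart_hu: float = 75.0
    ctv2_hu: float = 25.0
    ctv1_hu: float = 55.0
    texture_amplitude: float = 8.0
    texture_scale_mm: float = 6.0
    seed: int = 0

    def resolved_body(self) -> Tuple[Tuple[float, ...], Tuple[float, ...]]:
        ndim = len(self.shape)
        extent = [self.shape[a] * self.spacing[a] for a in range(ndim)]
        center = self.body_center or tuple(e / 2 for e in extent)
        radii = self.body_radii or tuple(0.45 * e for e in extent)
        return tuple(center), tuple(radii)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomConfig":
        d = yaml.safe_load(text)
        for k in ("shape", "spacing", "body_center", "body_radii",
                  "heart_center_offset", "ctv2_center_offset", "ctv1_center_offset"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class ArtifactConfig:
    """CBCT degradation model: shading bias, streaks, noise, contrast loss.

    The all-zero configuration (``contrast_compression=1``) is the identity.
    """

    shading_amplitude: float = 0.0    # HU, max |bias field|
    noise_sigma: float = 0.0          # HU, additive Gaussian
    streak_count: int = 0
    streak_amplitude: float = 0.0     # HU
    streak_width_mm: float = 1.5
    contrast_compression: float = 1.0  # in (0, 1]; applied about `contrast_pivot`
    contrast_pivot: float = 0.0        # HU value left fixed by compression
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 < self.contrast_compression <= 1.0):
            raise ValueError("contrast_compression must be in (0, 1]")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArtifactConfig":
        return cls(**yaml.safe_load(text))


def _ellipsoid_mask(grid: ImageGrid, center_mm, radii_mm) -> np.ndarray:
    coords = grid.physical_coords()
    q = np.zeros(grid.shape)
    for a in range(grid.ndim):
        q += ((coords[a] - center_mm[a]) / radii_mm[a]) ** 2
    return (q <= 1.0).astype(np.uint8)


def generate_phantom(config: PhantomConfig) -> Tuple[ImageGrid, StructureSet]:
    """Build a clean pCT-like phantom and its nested structure masks.

    Returns an :class:`ImageGrid` with piecewise-constant tissues plus smooth
    texture and a :class:`StructureSet` with ``body``, ``heart``, ``CTV2``,
    ``CTV1``. Deterministic for a fixed ``config.seed``.
    """
    ndim = len(config.shape)
    if len(config.spacing) != ndim:
        raise ValueError("shape and spacing rank mismatch")
    grid = ImageGrid(np.zeros(config.shape), config.spacing, (0.0,) * ndim)
    body_center, body_radii = config.resolved_body()

    def off(offset):
        o = tuple(offset)[:ndim] + (0.0,) * max(0, ndim - len(offset))
        return tuple(body_center[a] + o[a] for a in range(ndim))

    body = _ellipsoid_mask(grid, body_center, body_radii)
    heart = _ellipsoid_mask(grid, off(config.heart_center_offset), (config.heart_radius,) * ndim)
    ctv2 = _ellipsoid_mask(grid, off(config.ctv2_center_offset), (config.ctv2_radius,) * ndim)
    ctv1 = _ellipsoid_mask(grid, off(config.ctv1_center_offset), (config.ctv1_radius,) * ndim)

    # nesting: every structure clipped to body, CTV1 to CTV2
    heart &= body
    ctv2 &= body
    ctv1 &= ctv2
    if not ctv1.any() or not ctv2.any() or not heart.any():
        raise ValueError("structure geometry cannot be nested inside the body with this config")

    values = np.full(config.shape, config.air_hu)
    values[body > 0] = config.body_hu
    values[heart > 0] = config.heart_hu
    values[ctv2 > 0] = config.ctv2_hu
    values[ctv1 > 0] = config.ctv1_hu

    if config.texture_amplitude > 0:
        rng = np.random.default_rng(config.seed)
        noise = rng.standard_normal(config.shape)
        sigma_vox = [config.texture_scale_mm / s for s in config.spacing]
        tex = gaussian_filter(noise, sigma_vox)
        std = tex.std()
        if std > 0:
            tex *= config.texture_amplitude / std
        values = values + tex * (body > 0)

    image = ImageGrid(values, config.spacing, (0.0,) * ndim)
    structures = StructureSet({"body": body, "heart": heart, "CTV2": ctv2, "CTV1": ctv1})
    return image, structures


def _boundary_taper(shape, spacing, margin_mm: float) -> np.ndarray:
    """Smooth [0,1] window, exactly zero on the domain boundary."""
    taper = np.ones(shape)
    for a, n in enumerate(shape):
        d = np.minimum(np.arange(n), np.arange(n)[::-1]) * spacing[a]
        w = np.clip(d / max(margin_mm, spacing[a]), 0.0, 1.0)
        w = 0.5 - 0.5 * np.cos(np.pi * w)  # cosine ramp, 0 at edge
        sh = [1] * len(shape)
        sh[a] = n
        taper = taper * w.reshape(sh)
    return taper


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """det(grad(Id + u)) by central finite differences, spacing-aware."""
    u = field.vectors
    ndim = field.ndim
    J = np.zeros(field.grid_shape + (ndim, ndim))
    for comp in range(ndim):
        for axis in range(ndim):
            J[..., comp, axis] = np.gradient(u[..., comp], field.spacing[axis], axis=axis)
        J[..., comp, comp] += 1.0
    return np.linalg.det(J)


def sample_smooth_deformation(
    grid_shape,
    spacing,
    amplitude_mm: float,
    smoothness_mm: float,
    seed: int = 0,
) -> DisplacementField:
    """Smooth random displacement, zero at the boundary, max |u| = amplitude_mm.

    Components are Gaussian-filtered white noise (kernel width
    ``smoothness_mm``), tapered to zero at the domain boundary and rescaled so
    the maximum displacement magnitude equals ``amplitude_mm``. A warning is
    logged (not raised) if the resulting map folds (non-positive Jacobian).
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    if smoothness_mm <= 0:
        raise ValueError("smoothness_mm must be > 0")
    grid_shape = tuple(int(n) for n in grid_shape)
    ndim = len(grid_shape)
    spacing = tuple(float(s) for s in spacing)
    if amplitude_mm == 0:
        return DisplacementField.zeros(grid_shape, spacing)

    rng = np.random.default_rng(seed)
    sigma_vox = [smoothness_mm / s for s in spacing]
    u = np.zeros(grid_shape + (ndim,))
    for a in range(ndim):
        u[..., a] = gaussian_filter(rng.standard_normal(grid_shape), sigma_vox)
    u *= _boundary_taper(grid_shape, spacing, margin_mm=2 * smoothness_mm)[..., None]
    mag = np.sqrt((u**2).sum(axis=-1))
    peak = mag.max()
    if peak > 0:
        u *= amplitude_mm / peak
    field = DisplacementField(u, spacing)
    min_jac = jacobian_determinant(field).min()
    if min_jac <= 0:
        logger.warning(
            "sampled deformation folds: min Jacobian determinant %.4f <= 0 "
            "(amplitude %.1f mm, smoothness %.1f mm)", min_jac, amplitude_mm, smoothness_mm
        )
    return field


def degrade_to_cbct(image: ImageGrid, config: ArtifactConfig) -> ImageGrid:
    """Apply the CBCT degradation model; grid geometry is unchanged.

    output = contrast-compressed image + shading bias + streaks + noise.
    Deterministic given ``config.seed``; the all-zero config is the identity.
    """
    values = image.values.copy()
    ndim = image.ndim
    rng = np.random.default_rng(config.seed)

    if config.contrast_compression < 1.0:
        values = config.contrast_pivot + config.contrast_compression * (values - config.contrast_pivot)

    if config.shading_amplitude > 0:
        # low-frequency bias: heavily blurred random field, peak-normalised
        coarse_shape = tuple(max(2, n // 16) for n in image.shape)
        coarse = rng.standard_normal(coarse_shape)
        bias = np.asarray(coarse)
        zoom = [n / c for n, c in zip(image.shape, coarse_shape)]
        from scipy.ndimage import zoom as nd_zoom

        bias = nd_zoom(bias, zoom, order=3, mode="nearest")
        bias = bias[tuple(slice(0, n) for n in image.shape)]
        pad = [(0, n - b) for n, b in zip(image.shape, bias.shape)]
        if any(p[1] > 0 for p in pad):
            bias = np.pad(bias, pad, mode="edge")
        bias = gaussian_filter(bias, [n / 8 for n in image.shape])
        peak = np.abs(bias).max()
        if peak > 0:
            bias *= config.shading_amplitude / peak
        values = values + bias

    if config.streak_count > 0 and config.streak_amplitude != 0:
        coords = image.physical_coords()
        center = [image.origin[a] + 0.5 * image.shape[a] * image.spacing[a] for a in range(ndim)]
        for _ in range(config.streak_count):
            theta = rng.uniform(0, np.pi)
            n0, n1 = np.cos(theta), np.sin(theta)
            offset = rng.uniform(-0.25, 0.25) * min(image.shape[a] * image.spacing[a] for a in range(2))
            # signed distance to an oriented line in the first two axes
            d = n0 * (coords[0] - center[0]) + n1 * (coords[1] - center[1]) - offset
            profile = np.exp(-0.5 * (d / config.streak_width_mm) ** 2)
            sign = rng.choice([-1.0, 1.0])
            values = values + sign * config.streak_amplitude * profile

    if config.noise_sigma > 0:
        values = values + rng.normal(0.0, config.noise_sigma, size=image.shape)

    return image.with_values(values)


def stack_slices(slice_image: ImageGrid, n_slices: int, slice_spacing_mm: float = 5.0) -> ImageGrid:
    """Stack a 2D slice into a 3D volume (slice axis last, CT-convention 5 mm slice spacing)."""
    if slice_image.ndim != 2:
        raise ValueError("stack_slices expects a 2D image")
    vol = np.repeat(slice_image.values[:, :, None], n_slices, axis=2)
    return ImageGrid(
        vol,
        spacing=slice_image.spacing + (slice_spacing_mm,),
        origin=slice_image.origin + (0.0,),
    )
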