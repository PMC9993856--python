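"""Core domain types shared by all pipeline stages.

The common currency is :class:`ImageGrid` — a scalar volume together with its
voxel spacing and physical origin. Physical position of voxel index ``i`` along
axis ``a`` is ``origin[a] + i * spacing[a]`` (0-based indices, millimetres).
Displacement and velocity fields store per-voxel vectors in millimetres along
the physical axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Tuple

import numpy as np

__all__ = [
    "ImageGrid",
    "StructureSet",
    "DisplacementField",
    "VelocityField",
]


def _as_tuple(x, ndim: int) -> Tuple[float, ...]:
    if np.isscalar(x):
        return (float(x),) * ndim
    t = tuple(float(v) for v in x)
    if len(t) != ndim:
        raise ValueError(f"expected {ndim} components, got {len(t)}")
    return t


@dataclass(frozen=True)
class ImageGrid:
    """A scalar image with voxel spacing (mm) and physical origin (mm)."""

    values: np.ndarray
    spacing: Tuple[float, ...] = (1.0, 1.0)
    origin: Tuple[float, ...] = (0.0, 0.0)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        ndim = values.ndim
        if ndim not in (2, 3):
            raise ValueError(f"ImageGrid supports 2D/3D arrays, got ndim={ndim}")
        spacing = _as_tuple(self.spacing, ndim)
        origin = _as_tuple(self.origin, ndim)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        if not np.all(np.isfinite(values)):
            raise ValueError("ImageGrid values must be finite")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape

    def same_geometry(self, other: "ImageGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        """Same geometry, new intensities."""
        return ImageGrid(values, self.spacing, self.origin)

    def index_coords(self) -> List[np.ndarray]:
        """Per-axis voxel index grids (float), shape == self.shape each."""
        return list(np.meshgrid(*[np.arange(n, dtype=np.float64) for n in self.shape], indexing="ij"))

    def physical_coords(self) -> List[np.ndarray]:
        """Per-axis physical coordinate grids in mm."""
        return [self.origin[a] + self.spacing[a] * idx for a, idx in enumerate(self.index_coords())]


@dataclass
class StructureSet:
    """Named binary masks sharing one :class:`ImageGrid` geometry."""

    masks: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean: Dict[str, np.ndarray] = {}
        shape = None
        for name, mask in self.masks.items():
            arr = np.asarray(mask)
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask {name!r} has values outside {{0,1}}: {uniq}")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(f"mask {name!r} shape {arr.shape} != {shape}")
            clean[name] = arr.astype(np.uint8)
        self.masks = clean

    @property
    def names(self) -> List[str]:
        return list(self.masks.keys())

    @property
    def shape(self):
        for m in self.masks.values():
            return m.shape
        return None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def items(self):
        return self.masks.items()


@dataclass(frozen=True)
class DisplacementField:
    """Per-voxel displacement u (mm); the transform is phi = Id + u.

    ``vectors`` has shape ``grid_shape + (ndim,)``; component ``a`` is the
    displacement along physical axis ``a``.
    """

    vectors: np.ndarray
    spacing: Tuple[float, ...] = (1.0, 1.0)
    origin: Tuple[float, ...] = (0.0, 0.0)

    def __post_init__(self):
        vec = np.asarray(self.vectors, dtype=np.float64)
        object.__setattr__(self, "vectors", vec)
        ndim = vec.ndim - 1
        if ndim not in (2, 3) or vec.shape[-1] != ndim:
            raise ValueError(
                f"vectors must have shape grid_shape + (ndim,), got {vec.shape}"
            )
        object.__setattr__(self, "spacing", _as_tuple(self.spacing, ndim))
        object.__setattr__(self, "origin", _as_tuple(self.origin, ndim))
        if not np.all(np.isfinite(vec)):
            raise ValueError("displacement vectors must be finite")

    @property
    def ndim(self) -> int:
        return self.vectors.shape[-1]

    @property
    def grid_shape(self) -> Tuple[int, ...]:
        return self.vectors.shape[:-1]

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=-1))

    @classmethod
    def zeros(cls, grid_shape, spacing, origin=None) -> "DisplacementField":
        grid_shape = tuple(int(n) for n in grid_shape)
        ndim = len(grid_shape)
        if origin is None:
            origin = (0.0,) * ndim
        return cls(np.zeros(grid_shape + (ndim,)), spacing, origin)


class VelocityField(DisplacementField):
    """Stationary velocity field (mm); its exponential is a DisplacementField."""

    @classmethod
    def zeros(cls, grid_shape, spacing, origin=None) -> "VelocityField":
        grid_shape = tuple(int(n) for n in grid_shape)
        ndim = len(grid_shape)
        if origin is None:
            origin = (0.0,) * ndim
        return cls(np.zeros(grid_shape + (ndim,)), spacing, origin)
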