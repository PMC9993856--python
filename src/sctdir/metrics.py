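"""Segmentation overlap and surface-distance metrics.

Conventions (fixed here because they vary across the literature and silently
change values):

- the surface of a mask is its set of border voxels — mask voxels with at
  least one non-mask face-neighbour (edges of the array count as outside);
- HD95 and ASD are taken over the *pooled symmetric* multiset of directed
  border-to-border distances (A→B together with B→A);
- percentiles use linear interpolation on the pooled sorted values;
- distances are physical (mm), computed with the grid spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, distance_transform_edt, generate_binary_structure

from .core import StructureSet

__all__ = [
    "dsc",
    "border_voxels",
    "surface_distances",
    "hd95",
    "asd",
    "StructureMetrics",
    "MetricsReport",
    "evaluate_structures",
    "aggregate_cases",
]


def _check_masks(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Both masks empty → 1.0 (with a warning); exactly one empty → 0.0.
    """
    a, b = _check_masks(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        warnings.warn("dsc: both masks empty, returning 1.0", RuntimeWarning)
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def border_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >= 1 non-mask face-neighbour (array edge counts as outside)."""
    mask = np.asarray(mask).astype(bool)
    structure = generate_binary_structure(mask.ndim, 1)  # face connectivity
    interior = binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def surface_distances(a: np.ndarray, b: np.ndarray,
                      spacing: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Directed border-to-border distance multisets (mm), A→B and B→A."""
    a, b = _check_masks(a, b)
    if not a.any() or not b.any():
        raise ValueError("surface_distances requires two nonempty masks")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != a.ndim or any(s <= 0 for s in spacing):
        raise ValueError(f"invalid spacing {spacing} for rank-{a.ndim} masks")
    border_a = border_voxels(a)
    border_b = border_voxels(b)
    # EDT of the complement of each border gives the exact Euclidean distance
    # to the nearest border voxel centre, in mm via `sampling`.
    dist_to_b = distance_transform_edt(~border_b, sampling=spacing)
    dist_to_a = distance_transform_edt(~border_a, sampling=spacing)
    return dist_to_b[border_a], dist_to_a[border_b]


def _pooled(a, b, spacing) -> np.ndarray:
    d_ab, d_ba = surface_distances(a, b, spacing)
    return np.concatenate([d_ab, d_ba])


def hd95(a: np.ndarray, b: np.ndarray, spacing: Sequence[float]) -> float:
    """95th percentile (linear interpolation) of the pooled symmetric distances."""
    return float(np.percentile(_pooled(a, b, spacing), 95, method="linear"))


def asd(a: np.ndarray, b: np.ndarray, spacing: Sequence[float]) -> float:
    """Mean of the pooled symmetric surface-distance multiset."""
    return float(np.mean(_pooled(a, b, spacing)))


@dataclass
class StructureMetrics:
    dsc: Optional[float]
    hd95_mm: Optional[float]
    asd_mm: Optional[float]
    missing: bool = False


@dataclass
class MetricsReport:
    """Per-structure DSC/HD95/ASD, ordered like the reporting schema."""

    structures: Dict[str, StructureMetrics] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.structures.items():
            rows.append({"structure": name, "DSC": m.dsc, "HD95_mm": m.hd95_mm,
                         "ASD_mm": m.asd_mm, "missing": m.missing})
        return pd.DataFrame(rows)

    def present(self) -> Dict[str, StructureMetrics]:
        return {k: v for k, v in self.structures.items() if not v.missing}


DEFAULT_STRUCTURE_ORDER = ("CTV1", "CTV2", "heart")


def evaluate_structures(predicted: StructureSet, reference: StructureSet,
                        spacing: Sequence[float],
                        order: Sequence[str] = DEFAULT_STRUCTURE_ORDER) -> MetricsReport:
    """Per-structure metrics between propagated and reference contours.

    Structures missing on either side (or empty) are recorded as missing and
    excluded from aggregates, with a warning.
    """
    report = MetricsReport()
    names = [n for n in order if n in predicted or n in reference]
    for n in predicted.names:
        if n not in names and n != "body":
            names.append(n)
    for name in names:
        if name not in predicted or name not in reference:
            warnings.warn(f"structure {name!r} missing on one side; excluded", RuntimeWarning)
            report.structures[name] = StructureMetrics(None, None, None, missing=True)
            continue
        p, r = predicted[name], reference[name]
        d = dsc(p, r)
        if p.sum() == 0 or r.sum() == 0:
            warnings.warn(f"structure {name!r} empty; distances undefined", RuntimeWarning)
            report.structures[name] = StructureMetrics(d, None, None, missing=True)
            continue
        report.structures[name] = StructureMetrics(
            dsc=d, hd95_mm=hd95(p, r, spacing), asd_mm=asd(p, r, spacing)
        )
    return report


def aggregate_cases(reports: List[MetricsReport],
                    order: Sequence[str] = DEFAULT_STRUCTURE_ORDER) -> pd.DataFrame:
    """Cohort mean ± SD per structure plus an 'Average' row over structures.

    SD is over per-case values. The Average row first averages the per-case
    metrics over structures, then aggregates across cases.
    """
    rows = []
    per_case_avgs: Dict[str, List[float]] = {"DSC": [], "HD95_mm": [], "ASD_mm": []}
    values: Dict[str, Dict[str, List[float]]] = {}
    for rep in reports:
        case_vals: Dict[str, List[float]] = {"DSC": [], "HD95_mm": [], "ASD_mm": []}
        for name, m in rep.present().items():
            values.setdefault(name, {"DSC": [], "HD95_mm": [], "ASD_mm": []})
            values[name]["DSC"].append(m.dsc)
            values[name]["HD95_mm"].append(m.hd95_mm)
            values[name]["ASD_mm"].append(m.asd_mm)
            case_vals["DSC"].append(m.dsc)
            case_vals["HD95_mm"].append(m.hd95_mm)
            case_vals["ASD_mm"].append(m.asd_mm)
        for k, v in case_vals.items():
            if v:
                per_case_avgs[k].append(float(np.mean(v)))
    names = [n for n in order if n in values] + [n for n in values if n not in order]
    for name in names:
        row = {"structure": name}
        for k in ("DSC", "HD95_mm", "ASD_mm"):
            arr = np.asarray(values[name][k], dtype=float)
            row[f"{k}_mean"] = float(arr.mean())
            row[f"{k}_sd"] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        rows.append(row)
    if per_case_avgs["DSC"]:
        row = {"structure": "Average"}
        for k in ("DSC", "HD95_mm", "ASD_mm"):
            arr = np.asarray(per_case_avgs[k], dtype=float)
            row[f"{k}_mean"] = float(arr.mean())
            row[f"{k}_sd"] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
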