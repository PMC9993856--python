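"""Canonical desk-scale benchmark experiments.

These fix the configurations used to validate the pipeline's quantitative
claims at laptop scale: exponential-map accuracy against a dense ODE
integrator, recovery of known smooth deformations, translation fidelity after
micro-training, and the two-arm cohort comparison. Both the acceptance tests
and ``scripts/acceptance.py`` call into this module so the numbers they
report come from one place.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np

from .core import ImageGrid, VelocityField
from .demons import DemonsConfig, exp_velocity, register_diffeodemons, warp_image
from .phantom import (
    ArtifactConfig, PhantomConfig, degrade_to_cbct, generate_phantom,
    jacobian_determinant, sample_smooth_deformation,
)
from .pipeline import ExperimentConfig, build_training_slices, make_phantom_case, run_cohort
from .translation import GeneratorSpec, LossConfig, TrainConfig, train_translation, translate

__all__ = [
    "exp_map_errors",
    "registration_recovery",
    "micro_training_run",
    "cohort_comparison",
    "DEFAULT_ARTIFACTS",
]

# artifact severity used across the desk-scale experiments
DEFAULT_ARTIFACTS = ArtifactConfig(
    shading_amplitude=60.0, noise_sigma=15.0, streak_count=4,
    streak_amplitude=40.0, contrast_compression=0.5,
)


def exp_map_errors(squaring_steps: Sequence[int] = (2, 4, 6, 8), n: int = 32,
                   euler_substeps: int = 10_000) -> Dict[int, float]:
    """Max interior error (voxels) of scaling-and-squaring vs dense Euler
    integration of the flow ODE, for a linear velocity field on an n^2 grid."""
    A = np.array([[0.08, 0.03], [-0.02, 0.05]])
    x0 = np.array([(n - 1) / 2.0] * 2)
    idx = np.stack(np.meshgrid(np.arange(n), np.arange(n), indexing="ij"), -1).astype(float)
    v = (idx - x0) @ A.T
    pos = idx.copy()
    for _ in range(euler_substeps):
        pos = pos + ((pos - x0) @ A.T) / euler_substeps
    euler = pos - idx
    interior = (slice(n // 5, -n // 5), slice(n // 5, -n // 5))
    out = {}
    for k in squaring_steps:
        u = exp_velocity(VelocityField(v, (1.0, 1.0)), k)
        out[k] = float(np.abs(u.vectors - euler)[interior].max())
    return out


def registration_recovery(seed: int = 7, shape: Tuple[int, int] = (128, 128),
                          amplitude_mm: float = 3.0) -> Dict[str, float]:
    """Deform a phantom by a known smooth field and recover it with demons."""
    img, st = generate_phantom(PhantomConfig(shape=shape, seed=seed))
    gt = sample_smooth_deformation(img.shape, img.spacing, amplitude_mm, 20.0, seed=seed)
    fixed = warp_image(img, gt, "linear")
    dvf, diag = register_diffeodemons(fixed, img, DemonsConfig())
    ssd0 = float(np.sum((img.values - fixed.values) ** 2))
    ssd1 = float(np.sum((warp_image(img, dvf).values - fixed.values) ** 2))
    body = st["body"] > 0
    err = np.sqrt(((dvf.vectors - gt.vectors) ** 2).sum(-1))
    return {
        "ssd_ratio": ssd1 / ssd0,
        "mean_dvf_error_vox": float(err[body].mean()),  # 1 mm spacing
        "min_jacobian": float(jacobian_determinant(dvf).min()),
    }


def _micro_experiment_config(seed: int) -> ExperimentConfig:
    return ExperimentConfig(
        seed=seed,
        phantom=PhantomConfig(shape=(64, 64)),
        artifacts=DEFAULT_ARTIFACTS,
        deformation_amplitude_mm=3.0,
        deformation_smoothness_mm=20.0,
        n_train_slices=40,
        generator=GeneratorSpec(base_channels=8, n_res_blocks=1),
        train=TrainConfig(total_epochs=8, warm_epochs=4, seed=seed),
    )


def micro_training_run(seed: int, n_eval_cases: int = 5) -> Dict[str, float]:
    """Train on a 40-slice 64x64 phantom cohort; compare MAE(sCT, CT) against
    MAE(CBCT, CT) on held-out cases."""
    config = _micro_experiment_config(seed)
    xs, ys = build_training_slices(config, seed=seed)
    model, _ = train_translation(xs, ys, config.generator, config.loss, config.train)
    mae_cbct, mae_sct = [], []
    for j in range(n_eval_cases):
        case = make_phantom_case(config, case_seed=900_000 + j)
        sct = translate(case.cbct, model)
        mae_cbct.append(np.abs(case.cbct.values - case.fraction.values).mean())
        mae_sct.append(np.abs(sct.values - case.fraction.values).mean())
    return {
        "mae_cbct": float(np.mean(mae_cbct)),
        "mae_sct": float(np.mean(mae_sct)),
        "improved": bool(np.mean(mae_sct) < np.mean(mae_cbct)),
    }


def cohort_comparison(seed: int = 11, n_cases: int = 20) -> Dict[str, object]:
    """Two-arm 64x64 phantom cohort at default artifact severity.

    Returns per-arm mean DSC for the innermost (CTV1) structure and the full
    summary frame.
    """
    config = _micro_experiment_config(seed)
    config.n_cases = n_cases
    result = run_cohort(config)
    per_case = result["per_case"]
    out: Dict[str, object] = {"summary": result["summary"], "failed": result["failed"]}
    for arm in ("A", "B"):
        sel = per_case[(per_case.arm == arm) & (per_case.structure == "CTV1")]
        out[f"ctv1_dsc_{arm}"] = float(sel.DSC.mean())
        sel_all = per_case[per_case.arm == arm]
        out[f"mean_dsc_{arm}"] = float(sel_all.DSC.mean())
    return out
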