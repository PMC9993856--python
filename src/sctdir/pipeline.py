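"""Two-arm registration experiment orchestration.

Arm A registers the planning image directly to the degraded CBCT-like image;
arm B first translates the CBCT to a synthetic CT and registers to that. Both
arms share identical demons settings (asserted programmatically), propagate
the planning contours with their DVF, and are scored against reference
contours obtained by applying the ground-truth deformation.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .core import DisplacementField, ImageGrid, StructureSet
from .demons import DemonsConfig, register_diffeodemons, warp_image, warp_structures
from .metrics import MetricsReport, aggregate_cases, evaluate_structures
from .phantom import (
    ArtifactConfig, PhantomConfig, degrade_to_cbct, generate_phantom,
    sample_smooth_deformation,
)
from .translation import (
    GeneratorSpec, LossConfig, TrainConfig, TranslationModel, train_translation, translate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig", "PhantomCase", "make_phantom_case", "jitter_phantom_config",
    "build_training_slices", "run_case", "run_cohort", "config_hash",
]


def config_hash(config: DemonsConfig) -> str:
    return hashlib.sha256(yaml.safe_dump(asdict(config), sort_keys=True).encode()).hexdigest()


@dataclass
class ExperimentConfig:
    """Phantom-cohort experiment: data generation + training + registration."""

    n_cases: int = 20
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    artifacts: ArtifactConfig = field(default_factory=lambda: ArtifactConfig(
        shading_amplitude=60.0, noise_sigma=15.0, streak_count=4,
        streak_amplitude=40.0, contrast_compression=0.5))
    deformation_amplitude_mm: float = 3.0
    deformation_smoothness_mm: float = 20.0
    n_train_slices: int = 40
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        total_epochs=8, warm_epochs=4))
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    demons: DemonsConfig = field(default_factory=lambda: DemonsConfig(
        levels=2, iterations_per_level=30))
    output_dir: Optional[str] = None
    save_volumes: bool = False


@dataclass
class PhantomCase:
    """One synthetic patient: planning image, degraded fraction image, truth."""

    pct: ImageGrid
    pct_structures: StructureSet
    fraction: ImageGrid              # deformed clean anatomy at treatment time
    reference_structures: StructureSet  # pct contours under the true deformation
    cbct: ImageGrid                  # degraded fraction image
    true_deformation: DisplacementField


def jitter_phantom_config(base: PhantomConfig, rng: np.random.Generator) -> PhantomConfig:
    """Vary structure positions/sizes slightly so the cohort is not one anatomy."""
    def j(vals, scale):
        return tuple(float(v + rng.uniform(-scale, scale)) for v in vals)

    return PhantomConfig(
        shape=base.shape, spacing=base.spacing,
        body_center=base.body_center, body_radii=base.body_radii,
        heart_center_offset=j(base.heart_center_offset, 2.0),
        heart_radius=float(base.heart_radius * rng.uniform(0.9, 1.1)),
        ctv2_center_offset=j(base.ctv2_center_offset, 2.0),
        ctv2_radius=float(base.ctv2_radius * rng.uniform(0.9, 1.1)),
        ctv1_center_offset=j(base.ctv1_center_offset, 1.5),
        ctv1_radius=float(base.ctv1_radius * rng.uniform(0.9, 1.1)),
        air_hu=base.air_hu, body_hu=base.body_hu, heart_hu=base.heart_hu,
        ctv2_hu=base.ctv2_hu, ctv1_hu=base.ctv1_hu,
        texture_amplitude=base.texture_amplitude,
        texture_scale_mm=base.texture_scale_mm,
        seed=int(rng.integers(2**31)),
    )


def make_phantom_case(config: ExperimentConfig, case_seed: int) -> PhantomCase:
    """Generate one case: phantom, true deformation, references, CBCT."""
    rng = np.random.default_rng(case_seed)
    pconf = jitter_phantom_config(config.phantom, rng)
    pct, structures = generate_phantom(pconf)
    true_def = sample_smooth_deformation(
        pct.shape, pct.spacing, config.deformation_amplitude_mm,
        config.deformation_smoothness_mm, seed=int(rng.integers(2**31)),
    )
    fraction = warp_image(pct, true_def, "linear")
    reference = warp_structures(structures, true_def)
    art = ArtifactConfig(**{**asdict(config.artifacts), "seed": int(rng.integers(2**31))})
    cbct = degrade_to_cbct(fraction, art)
    return PhantomCase(pct, structures, fraction, reference, cbct, true_def)


def build_training_slices(config: ExperimentConfig, seed: int
                          ) -> Tuple[List[ImageGrid], List[ImageGrid]]:
    """Unpaired training pools: degraded (X) and clean (Y) phantom slices."""
    rng = np.random.default_rng(seed)
    xs: List[ImageGrid] = []
    ys: List[ImageGrid] = []
    for _ in range(config.n_train_slices):
        pconf = jitter_phantom_config(config.phantom, rng)
        clean, _ = generate_phantom(pconf)
        deform = sample_smooth_deformation(
            clean.shape, clean.spacing, config.deformation_amplitude_mm,
            config.deformation_smoothness_mm, seed=int(rng.integers(2**31)))
        art = ArtifactConfig(**{**asdict(config.artifacts), "seed": int(rng.integers(2**31))})
        xs.append(degrade_to_cbct(warp_image(clean, deform, "linear"), art))
        # unpaired Y pool: an independent clean phantom
        yconf = jitter_phantom_config(config.phantom, rng)
        yclean, _ = generate_phantom(yconf)
        ys.append(yclean)
    return xs, ys


def run_case(pct: ImageGrid, cbct: ImageGrid, pct_contours: StructureSet,
             reference_contours: StructureSet, model: Optional[TranslationModel],
             demons_config: DemonsConfig) -> Dict[str, Dict]:
    """Run both registration arms on one case.

    Arm A: fixed = CBCT. Arm B: fixed = translate(CBCT) (requires ``model``).
    The only difference between arms is the fixed image — asserted via config
    hash. Contours are propagated with nearest-neighbour warping.
    """
    arms: Dict[str, Dict] = {}
    fixed_images = {"A": cbct}
    if model is not None:
        t0 = time.perf_counter()
        sct = translate(cbct, model)
        logger.info("translation: %.2f s", time.perf_counter() - t0)
        fixed_images["B"] = sct
    arm_hashes = {}
    for arm, fixed in fixed_images.items():
        t0 = time.perf_counter()
        arm_hashes[arm] = config_hash(demons_config)
        dvf, diagnostics = register_diffeodemons(fixed, pct, demons_config)
        propagated = warp_structures(pct_contours, dvf)
        report = evaluate_structures(propagated, reference_contours, pct.spacing)
        logger.info("arm %s: registration + evaluation %.2f s", arm,
                    time.perf_counter() - t0)
        arms[arm] = {
            "fixed": fixed,
            "dvf": dvf,
            "warped": warp_image(pct, dvf, "linear"),
            "propagated": propagated,
            "report": report,
            "diagnostics": diagnostics,
            "config_hash": arm_hashes[arm],
        }
    if len(arm_hashes) == 2:
        assert arm_hashes["A"] == arm_hashes["B"], \
            "arms must share identical demons settings"
    return arms


def run_cohort(config: ExperimentConfig,
               model: Optional[TranslationModel] = None) -> Dict[str, object]:
    """Generate a phantom cohort, train (if no model given), run both arms per
    case, and aggregate per-structure metrics into a Table-style summary.

    Returns dict with 'summary' (DataFrame, arm x structure mean/SD),
    'per_case' (DataFrame) and 'model'. With >50% case failures the cohort is
    marked failed.
    """
    rng = np.random.default_rng(config.seed)
    if model is None:
        t0 = time.perf_counter()
        xs, ys = build_training_slices(config, seed=int(rng.integers(2**31)))
        model, _ = train_translation(xs, ys, config.generator, config.loss, config.train)
        logger.info("training: %.1f s", time.perf_counter() - t0)

    reports: Dict[str, List[MetricsReport]] = {"A": [], "B": []}
    rows = []
    n_failed = 0
    case_seeds = [int(rng.integers(2**31)) for _ in range(config.n_cases)]
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    for i, case_seed in enumerate(case_seeds):
        try:
            case = make_phantom_case(config, case_seed)
            arms = run_case(case.pct, case.cbct, case.pct_structures,
                            case.reference_structures, model, config.demons)
        except Exception as exc:
            n_failed += 1
            logger.error("case %d failed: %s", i, exc)
            rows.append({"case": i, "failed": True, "error": str(exc)})
            continue
        for arm, result in arms.items():
            reports[arm].append(result["report"])
            for name, m in result["report"].structures.items():
                rows.append({"case": i, "arm": arm, "structure": name,
                             "DSC": m.dsc, "HD95_mm": m.hd95_mm, "ASD_mm": m.asd_mm,
                             "failed": False})
        if out_dir and config.save_volumes:
            from .imageio import write_volume

            case_dir = out_dir / f"case_{i:03d}"
            write_volume(case.pct, case_dir / "pct.nii")
            write_volume(case.cbct, case_dir / "cbct.nii")
            for arm, result in arms.items():
                write_volume(result["warped"], case_dir / f"warped_{arm}.nii")

    failed = n_failed > config.n_cases / 2
    per_case = pd.DataFrame(rows)
    summaries = []
    for arm, reps in reports.items():
        if not reps:
            continue
        df = aggregate_cases(reps)
        df.insert(0, "arm", arm)
        summaries.append(df)
    summary = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    if out_dir:
        per_case.to_csv(out_dir / "per_case.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
    return {"summary": summary, "per_case": per_case, "model": model,
            "failed": failed, "n_failed": n_failed}
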