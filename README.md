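# sctdir

Synthetic-CT-assisted deformable image registration, end to end, on
desk-scale synthetic data:

1. **phantom** — 2D/3D digital phantoms: a clean planning-CT-like image with
   nested target structures (body ⊃ heart, CTV2 ⊃ CTV1), smooth random
   ground-truth deformations, and a CBCT-like degradation model (contrast
   compression, low-frequency shading, streaks, noise).
2. **imageio** — NIfTI I/O (nibabel), resampling, and rigid pre-alignment
   (MSD similarity, multi-start coordinate search + Nelder–Mead).
3. **translation** — contrastive unpaired CBCT→CT translation: a one-way
   ResNet-style generator, per-layer projection heads, a multi-layer patch
   contrastive loss (internal negatives, temperature 0.07), an adversarial
   loss, and an Adam training loop with a warm-then-linear-decay LR schedule.
   Runs on a small numpy reverse-mode autodiff engine (`sctdir.nn`) — no GPU
   or deep-learning framework required.
4. **demons** — log-domain diffeomorphic demons: SSD + smoothness energy,
   demons forces with fluid/diffusion smoothing, velocity-field exponential
   by scaling-and-squaring, multiresolution iteration, image/label warping.
5. **metrics** — DSC, HD95 and ASD with locked conventions
   (face-connectivity borders, pooled symmetric distance multisets, linear
   percentile interpolation, physical mm).
6. **pipeline** — the two-arm experiment: register planning image → CBCT
   directly (arm A) vs. translate CBCT → synthetic CT first (arm B), with
   identical demons settings, DVF contour propagation, and per-structure /
   cohort reporting.

## CLI

```sh
sctdir phantom --seed 1 --deformation-mm 3 --out scratch/case0
sctdir train --config experiment.yaml --out scratch/model.npz
sctdir translate --model scratch/model.npz --image scratch/case0/cbct.nii --out scratch/sct.nii
sctdir register --fixed scratch/sct.nii --moving scratch/case0/pct.nii --out-dvf scratch/dvf.nii
sctdir evaluate --predicted warped_CTV1.nii --reference ref_CTV1.nii --out metrics.csv
sctdir run-cohort --config experiment.yaml --out scratch/cohort
```

`experiment.yaml` mirrors `sctdir.pipeline.ExperimentConfig` (phantom cohort
parameters, artifact severity, training and demons settings); every
subcommand is seeded and reproducible.

## Library example

```python
from sctdir import (
    PhantomConfig, ArtifactConfig, generate_phantom, degrade_to_cbct,
    sample_smooth_deformation, warp_image, register_diffeodemons,
    DemonsConfig, evaluate_structures,
)

pct, structures = generate_phantom(PhantomConfig(seed=1))
truth = sample_smooth_deformation(pct.shape, pct.spacing, 3.0, 20.0, seed=2)
fraction = warp_image(pct, truth)
cbct = degrade_to_cbct(fraction, ArtifactConfig(noise_sigma=15, shading_amplitude=60, seed=3))
dvf, diagnostics = register_diffeodemons(cbct, pct, DemonsConfig())
```
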