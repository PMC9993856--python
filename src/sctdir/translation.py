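"""Contrastive unpaired CBCT-to-CT translation.

A one-way ResNet-style generator maps artifact-degraded slices to CT-quality
slices. Anatomy is preserved by a multi-layer patch contrastive loss: encoder
features of the *output* at sampled locations are queries, the *input*'s
features at the same locations are positives, and the input's features at the
other sampled locations of the same layer are the negatives (internal
negatives). An adversarial loss drives the output towards the CT intensity
distribution, and the same contrastive machinery applied to CT-domain images
acts as an identity term.

Total objective: L_GAN + lambda_x * L_patch(X) + lambda_y * L_patch(Y), with
defaults lambda_x = lambda_y = 1 and temperature 0.07.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .core import ImageGrid
from .nn import (
    Adam, PatchDiscriminator, ProjectionHead, ResnetGenerator, Tensor, logsumexp,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorSpec", "LossConfig", "TrainConfig", "FeatureStack", "TranslationModel",
    "patch_nce_loss", "encode_and_project", "multilayer_patchnce", "gan_loss",
    "total_loss", "train_translation", "translate", "lr_schedule",
    "normalize_intensities", "denormalize_intensities",
]


# --------------------------------------------------------------------- configs
@dataclass
class GeneratorSpec:
    """Architecture of the encoder/decoder generator and its feature taps."""

    base_channels: int = 16
    n_res_blocks: int = 2
    n_down: int = 2
    # encoder tap indices used by the contrastive loss: 0 = input image,
    # 1 = stem, 2..n_down+1 = downsampling stages, n_down+2 = residual core.
    tap_layers: Tuple[int, ...] = (0, 1, 2, 3)
    hu_window: Tuple[float, float] = (-1000.0, 200.0)

    def n_taps(self) -> int:
        return self.n_down + 3

    def __post_init__(self):
        if any(t < 0 or t >= self.n_taps() for t in self.tap_layers):
            raise ValueError(f"tap_layers {self.tap_layers} outside valid range "
                             f"[0, {self.n_taps() - 1}]")


@dataclass
class LossConfig:
    """Contrastive / adversarial loss weights and sampling parameters."""

    temperature: float = 0.07
    lambda_x: float = 1.0
    lambda_y: float = 1.0
    patches_per_layer: int = 64   # S_l; negatives per query are the other S_l - 1

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.lambda_x < 0 or self.lambda_y < 0:
            raise ValueError("loss weights must be >= 0")
        if self.patches_per_layer < 2:
            raise ValueError("patches_per_layer must be >= 2 so negatives exist")


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    total_epochs: int = 200
    warm_epochs: int = 50        # constant LR, then linear decay to 0
    batch_size: int = 1
    gan_mode: str = "vanilla"    # "vanilla" (log-prob) or "lsgan" (least squares)
    seed: int = 0
    checkpoint_dir: Optional[str] = None

    def __post_init__(self):
        if self.total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 <= self.warm_epochs <= self.total_epochs):
            raise ValueError("warm_epochs must lie in [0, total_epochs]")
        if self.gan_mode not in ("vanilla", "lsgan"):
            raise ValueError("gan_mode must be 'vanilla' or 'lsgan'")


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Learning rate at a 1-based epoch: constant for the warm epochs, then
    linear decay reaching exactly 0 at ``total_epochs``."""
    if epoch <= config.warm_epochs:
        return config.learning_rate
    span = config.total_epochs - config.warm_epochs
    return config.learning_rate * (config.total_epochs - epoch) / span


# --------------------------------------------------------------- feature stack
@dataclass
class FeatureStack:
    """Unit-norm projected feature vectors per tap layer.

    ``vectors[l]`` has shape (S_l, K); ``locations[l]`` are the flat spatial
    indices the vectors were sampled at; ``source`` tags input vs output.
    """

    vectors: List[np.ndarray]
    locations: List[np.ndarray]
    tap_layers: Tuple[int, ...]
    source: str = "input"

    def n_vectors(self) -> int:
        return sum(v.shape[0] for v in self.vectors)


# ----------------------------------------------------------------------- model
class TranslationModel:
    """Generator + per-tap projection heads + intensity window."""

    def __init__(self, spec: GeneratorSpec, loss_config: Optional[LossConfig] = None,
                 seed: int = 0):
        self.spec = spec
        self.loss_config = loss_config or LossConfig()
        rng = np.random.default_rng(seed)
        self.generator = ResnetGenerator(spec.base_channels, spec.n_res_blocks,
                                         spec.n_down, rng=rng)
        chans = self.generator.tap_channels()
        self.heads: Dict[int, ProjectionHead] = {
            t: ProjectionHead(chans[t], rng=rng) for t in spec.tap_layers
        }

    def parameters(self):
        params = self.generator.parameters()
        for head in self.heads.values():
            params.extend(head.parameters())
        return params

    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {f"G.{k}": v for k, v in self.generator.state_dict().items()}
        for t, head in self.heads.items():
            out.update({f"H{t}.{k}": v for k, v in head.state_dict().items()})
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        self.generator.load_state_dict(
            {k[2:]: v for k, v in state.items() if k.startswith("G.")})
        for t, head in self.heads.items():
            prefix = f"H{t}."
            head.load_state_dict(
                {k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)})

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **self.state_dict())
        meta = {"spec": asdict(self.spec), "loss_config": asdict(self.loss_config)}
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def load(cls, path) -> "TranslationModel":
        path = Path(path)
        meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
        spec_d = meta["spec"]
        spec_d["tap_layers"] = tuple(spec_d["tap_layers"])
        spec_d["hu_window"] = tuple(spec_d["hu_window"])
        model = cls(GeneratorSpec(**spec_d), LossConfig(**meta["loss_config"]))
        npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
        with np.load(npz_path) as data:
            model.load_state_dict(dict(data))
        return model


# ------------------------------------------------------------------ intensity
def normalize_intensities(values: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    """Map the HU window linearly onto [-1, 1], clipping outside it."""
    lo, hi = window
    return np.clip(2.0 * (values - lo) / (hi - lo) - 1.0, -1.0, 1.0)


def denormalize_intensities(values: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (np.asarray(values) + 1.0) * 0.5 * (hi - lo) + lo


# --------------------------------------------------------------------- losses
def patch_nce_loss(query: np.ndarray, positive: np.ndarray,
                   negatives: np.ndarray, temperature: float = 0.07) -> float:
    """(N+1)-way cross-entropy for one query against its positive and N
    negatives, computed with a stable log-sum-exp.

    Returns -log[ exp(q.p/t) / (exp(q.p/t) + sum_n exp(q.n/t)) ].
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    query = np.asarray(query, dtype=np.float64)
    positive = np.asarray(positive, dtype=np.float64)
    negatives = np.atleast_2d(np.asarray(negatives, dtype=np.float64))
    if negatives.shape[0] < 1:
        raise ValueError("at least one negative is required")
    logits = np.concatenate([[query @ positive], negatives @ query]) / temperature
    m = logits.max()
    return float(m + np.log(np.exp(logits - m).sum()) - logits[0])


def _nce_from_pairs(z_query: Tensor, z_keys: Tensor, temperature: float) -> Tensor:
    """Mean (N+1)-way cross-entropy with internal negatives.

    z_query, z_keys: (S, K) unit-row tensors; for row s the positive is
    z_keys[s] and the negatives are the other S-1 rows of z_keys.
    """
    logits = (z_query @ z_keys.T) * (1.0 / temperature)  # (S, S)
    s = logits.shape[0]
    eye = Tensor(np.eye(s))
    diag = (logits * eye).sum(axis=1, keepdims=True)     # (S, 1)
    lse = logsumexp(logits, axis=1, keepdims=True)       # (S, 1)
    return (lse - diag).mean()


def _sample_locations(tap_shapes: Sequence[Tuple[int, ...]], n_patches: int,
                      rng: np.random.Generator) -> List[np.ndarray]:
    locs = []
    for shape in tap_shapes:
        n_spatial = int(np.prod(shape[1:]))
        n = min(n_patches, n_spatial)
        locs.append(rng.choice(n_spatial, size=n, replace=False))
    return locs


def _project_taps(model: TranslationModel, taps: List[Tensor],
                  locations: List[np.ndarray]) -> List[Tensor]:
    out = []
    for tap_idx, locs in zip(model.spec.tap_layers, locations):
        fmap = taps[tap_idx]
        c = fmap.shape[0]
        flat = fmap.reshape(c, -1)
        sampled = flat.take_columns(locs).T  # (S, C)
        out.append(model.heads[tap_idx](sampled))
    return out


def encode_and_project(image: ImageGrid, model: TranslationModel,
                       sample_locations: List[np.ndarray],
                       loss_config: Optional[LossConfig] = None) -> FeatureStack:
    """Encode a 2D image and project tap features at the given locations.

    ``sample_locations[i]`` holds flat spatial indices into tap layer
    ``model.spec.tap_layers[i]``. Vectors are unit-normalised. Reusing the
    same locations for an input image and its translation makes positives
    correspond spatially.
    """
    if image.ndim != 2:
        raise ValueError("encode_and_project expects a 2D image")
    x = Tensor(normalize_intensities(image.values, model.spec.hu_window)[None])
    taps = model.generator.encode(x)
    vectors = []
    for tap_idx, locs in zip(model.spec.tap_layers, sample_locations):
        n_spatial = int(np.prod(taps[tap_idx].shape[1:]))
        locs = np.asarray(locs)
        if locs.size and (locs.min() < 0 or locs.max() >= n_spatial):
            raise IndexError(
                f"sample location out of range for tap {tap_idx} "
                f"(extent {n_spatial})")
    projected = _project_taps(model, taps, sample_locations)
    return FeatureStack(
        vectors=[p.data.copy() for p in projected],
        locations=[np.asarray(l) for l in sample_locations],
        tap_layers=model.spec.tap_layers,
        source="input",
    )


def _patchnce_tensor(model: TranslationModel, image_values: np.ndarray,
                     loss_config: LossConfig, rng: np.random.Generator,
                     return_output: bool = False):
    """L_patch for one normalised slice: encode it, translate it, re-encode the
    output, and contrast matching locations across the configured tap layers."""
    x = Tensor(image_values[None])
    taps_in = model.generator.encode(x)
    out = model.generator.decode(taps_in[-1])
    taps_out = model.generator.encode(out)
    tap_shapes = [taps_in[t].shape for t in model.spec.tap_layers]
    locations = _sample_locations(tap_shapes, loss_config.patches_per_layer, rng)
    z_in = _project_taps(model, taps_in, locations)       # positives/negatives
    z_out = _project_taps(model, taps_out, locations)     # queries
    total = None
    for zq, zk in zip(z_out, z_in):
        term = _nce_from_pairs(zq, zk, loss_config.temperature)
        total = term if total is None else total + term
    loss = total * (1.0 / len(model.spec.tap_layers))
    return (loss, out) if return_output else loss


def multilayer_patchnce(model: TranslationModel,
                        images: Sequence[ImageGrid],
                        loss_config: Optional[LossConfig] = None,
                        seed: int = 0) -> float:
    """Expectation over images of the multi-layer patch contrastive loss.

    For each sampled location the negatives are the other S_l - 1 locations of
    the same layer of the same image (internal negatives). The identity-domain
    variant is this same function applied to CT-domain images.
    """
    if not images:
        raise ValueError("at least one image required")
    loss_config = loss_config or model.loss_config
    rng = np.random.default_rng(seed)
    vals = []
    for img in images:
        norm = normalize_intensities(img.values, model.spec.hu_window)
        vals.append(_patchnce_tensor(model, norm, loss_config, rng).item())
    return float(np.mean(vals))


_EPS = 1e-7


def gan_loss(discriminator_outputs_real: np.ndarray,
             discriminator_outputs_fake: np.ndarray) -> float:
    """E[log D(y)] + E[log(1 - D(G(x)))] over probability-valued outputs.

    Outputs outside (0,1) are clamped with a logged warning (numerical guard).
    """
    d_real = np.asarray(discriminator_outputs_real, dtype=np.float64)
    d_fake = np.asarray(discriminator_outputs_fake, dtype=np.float64)
    if (d_real <= 0).any() or (d_real >= 1).any() or (d_fake <= 0).any() or (d_fake >= 1).any():
        logger.warning("gan_loss: discriminator outputs outside (0,1); clamping")
    d_real = np.clip(d_real, _EPS, 1 - _EPS)
    d_fake = np.clip(d_fake, _EPS, 1 - _EPS)
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


def _d_prob(logits: Tensor) -> Tensor:
    return logits.sigmoid().clip(_EPS, 1 - _EPS)


def total_loss(model: TranslationModel, discriminator: PatchDiscriminator,
               x_image: ImageGrid, y_image: ImageGrid,
               loss_config: Optional[LossConfig] = None,
               seed: int = 0) -> Tuple[float, Dict[str, float]]:
    """Full objective L_GAN + lambda_x L_patch(X) + lambda_y L_patch(Y) on one
    (x, y) pair, with the component breakdown for logging."""
    loss_config = loss_config or model.loss_config
    rng = np.random.default_rng(seed)
    window = model.spec.hu_window
    xn = normalize_intensities(x_image.values, window)
    yn = normalize_intensities(y_image.values, window)

    nce_x, fake = _patchnce_tensor(model, xn, loss_config, rng, return_output=True)
    nce_y = _patchnce_tensor(model, yn, loss_config, rng)
    d_real = _d_prob(discriminator(Tensor(yn[None])))
    d_fake = _d_prob(discriminator(fake.detach()))
    l_gan = gan_loss(d_real.data, d_fake.data)

    components = {
        "L_GAN": l_gan,
        "L_NCE_X": nce_x.item(),
        "L_NCE_Y": nce_y.item(),
    }
    total = l_gan + loss_config.lambda_x * components["L_NCE_X"] \
        + loss_config.lambda_y * components["L_NCE_Y"]
    return float(total), components


# -------------------------------------------------------------------- training
def _as_image_list(images) -> List[ImageGrid]:
    out = []
    for img in images:
        out.append(img if isinstance(img, ImageGrid) else ImageGrid(np.asarray(img)))
    return out


def train_translation(unpaired_x_images, unpaired_y_images,
              generator_spec: Optional[GeneratorSpec] = None,
              loss_config: Optional[LossConfig] = None,
              train_config: Optional[TrainConfig] = None
              ) -> Tuple[TranslationModel, List[Dict[str, float]]]:
    """Train the translation model on unpaired CBCT-like (X) and CT-like (Y)
    2D slices.

    Alternates discriminator and generator updates (one x and one y sampled
    independently per step, batch size 1). The learning rate is constant for
    the warm epochs then decays linearly to zero at the final epoch. Returns
    the trained model and a per-epoch log of loss components and LR. On a
    non-finite loss the run aborts, retaining the last finite-state weights.
    """
    x_images = _as_image_list(unpaired_x_images)
    y_images = _as_image_list(unpaired_y_images)
    if not x_images or not y_images:
        raise ValueError("both image sets must be nonempty")
    spec = generator_spec or GeneratorSpec()
    loss_config = loss_config or LossConfig()
    config = train_config or TrainConfig()
    rng = np.random.default_rng(config.seed)

    model = TranslationModel(spec, loss_config, seed=config.seed)
    min_spatial = min(min(img.shape) for img in x_images + y_images)
    disc = PatchDiscriminator(base_channels=spec.base_channels,
                              n_layers=PatchDiscriminator.layers_for(min_spatial),
                              rng=np.random.default_rng(config.seed + 1))
    opt_g = Adam(model.parameters(), lr=config.learning_rate,
                 betas=(config.beta1, config.beta2))
    opt_d = Adam(disc.parameters(), lr=config.learning_rate,
                 betas=(config.beta1, config.beta2))

    window = spec.hu_window
    xs = [normalize_intensities(img.values, window) for img in x_images]
    ys = [normalize_intensities(img.values, window) for img in y_images]

    log: List[Dict[str, float]] = []
    last_good = model.state_dict()
    vanilla = config.gan_mode == "vanilla"

    for epoch in range(1, config.total_epochs + 1):
        lr = lr_schedule(epoch, config)
        opt_g.lr = lr
        opt_d.lr = lr
        order = rng.permutation(len(xs))
        sums = {"L_GAN": 0.0, "L_NCE_X": 0.0, "L_NCE_Y": 0.0, "L_D": 0.0}
        aborted = False
        for step, ix in enumerate(order):
            xn = xs[ix]
            yn = ys[rng.integers(len(ys))]
            y_t = Tensor(yn[None])

            # --- generator forward (graph reused for D and G updates)
            nce_x, fake = _patchnce_tensor(model, xn, loss_config, rng, return_output=True)
            nce_y = _patchnce_tensor(model, yn, loss_config, rng)

            # --- discriminator update
            d_real_logit = disc(y_t)
            d_fake_logit = disc(fake.detach())
            if vanilla:
                d_loss = -(_d_prob(d_real_logit).log().mean()
                           + (1.0 - _d_prob(d_fake_logit)).log().mean())
            else:
                d_loss = ((d_real_logit - 1.0) ** 2).mean() + (d_fake_logit ** 2).mean()
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            # --- generator update (adversarial + contrastive terms)
            d_fake_logit2 = disc(fake)
            if vanilla:
                g_adv = -_d_prob(d_fake_logit2).log().mean()  # non-saturating form
            else:
                g_adv = ((d_fake_logit2 - 1.0) ** 2).mean()
            g_loss = g_adv + loss_config.lambda_x * nce_x + loss_config.lambda_y * nce_y
            opt_g.zero_grad()
            disc.zero_grad()  # fake passed through D; discard its grads
            g_loss.backward()
            opt_g.step()

            l_gan_value = gan_loss(_d_prob(d_real_logit).data, _d_prob(d_fake_logit).data)
            if not (np.isfinite(g_loss.item()) and np.isfinite(d_loss.item())):
                logger.error("non-finite loss at epoch %d step %d; aborting with "
                             "last checkpoint retained", epoch, step)
                model.load_state_dict(last_good)
                aborted = True
                break
            sums["L_GAN"] += l_gan_value
            sums["L_NCE_X"] += nce_x.item()
            sums["L_NCE_Y"] += nce_y.item()
            sums["L_D"] += d_loss.item()
        if aborted:
            break
        n_steps = len(order)
        entry = {"epoch": epoch, "LR": lr,
                 **{k: v / n_steps for k, v in sums.items()}}
        log.append(entry)
        last_good = model.state_dict()
        if config.checkpoint_dir:
            model.save(Path(config.checkpoint_dir) / "model_latest.npz")
        logger.info("epoch %d: LR %.2e, L_GAN %.3f, L_NCE_X %.3f, L_NCE_Y %.3f",
                    epoch, lr, entry["L_GAN"], entry["L_NCE_X"], entry["L_NCE_Y"])
    return model, log


# ------------------------------------------------------------------- inference
def translate(image: ImageGrid, model: TranslationModel) -> ImageGrid:
    """Translate a CBCT-like image to a synthetic-CT image.

    2D images go through the generator directly; 3D volumes are translated
    slice-by-slice along the last axis. Grid geometry is preserved.
    """
    window = model.spec.hu_window
    if image.ndim == 2:
        xn = normalize_intensities(image.values, window)
        out = model.generator(Tensor(xn[None]))
        values = denormalize_intensities(out.data[0], window)
    elif image.ndim == 3:
        slices = []
        for k in range(image.shape[2]):
            xn = normalize_intensities(image.values[:, :, k], window)
            out = model.generator(Tensor(xn[None]))
            slices.append(denormalize_intensities(out.data[0], window))
        values = np.stack(slices, axis=2)
    else:  # pragma: no cover
        raise ValueError("translate supports 2D and 3D images")
    if values.shape != image.shape:
        raise ValueError("generator changed the image shape; incompatible input size")
    return image.with_values(values)
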