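"""Network building blocks: conv / norm / MLP layers and the generator and
discriminator architectures used for CBCT-to-CT translation."""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from .tensor import Tensor, conv2d, upsample_nearest2x

__all__ = [
    "Module", "Conv2d", "InstanceNorm2d", "Linear",
    "ResidualBlock", "ResnetGenerator", "PatchDiscriminator", "ProjectionHead",
]


class Module:
    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> Dict[str, Tensor]:
        out: Dict[str, Tensor] = {}
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[name] = v
            elif isinstance(v, Module):
                out.update(v.named_parameters(f"{name}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{name}.{i}."))
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        for k, v in state.items():
            if k not in params:
                raise KeyError(f"unexpected parameter {k!r}")
            if params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            params[k].data[...] = v

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: Optional[int] = None, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(cout, cin, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class InstanceNorm2d(Module):
    """Per-channel spatial normalisation with learnable affine parameters."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((c, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((c, 1, 1)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=2, keepdims=True).mean(axis=1, keepdims=True)
        centred = x - mu
        var = (centred**2).mean(axis=2, keepdims=True).mean(axis=1, keepdims=True)
        return self.gamma * (centred / ((var + self.eps) ** 0.5)) + self.beta


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / fin)
        self.weight = Tensor(rng.normal(0.0, scale, size=(fin, fout)), requires_grad=True)
        # small random bias so an all-zero input still projects to a nonzero
        # (normalisable) vector
        self.bias = Tensor(rng.normal(0.0, 0.01, size=fout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ResidualBlock(Module):
    def __init__(self, c: int, rng: Optional[np.random.Generator] = None):
        self.conv1 = Conv2d(c, c, 3, rng=rng)
        self.norm1 = InstanceNorm2d(c)
        self.conv2 = Conv2d(c, c, 3, rng=rng)
        self.norm2 = InstanceNorm2d(c)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return x + h


class ResnetGenerator(Module):
    """Encoder / residual-core / decoder generator for 2D slices.

    The encoder taps (input image, each downsampling stage, residual core
    output) are the feature layers used by the patch-contrastive loss.
    """

    def __init__(self, base_channels: int = 16, n_res_blocks: int = 2,
                 n_down: int = 2, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.base_channels = base_channels
        self.n_down = n_down
        ch = base_channels
        self.stem = Conv2d(1, ch, 7, rng=rng)
        self.stem_norm = InstanceNorm2d(ch)
        self.down_convs: List[Module] = []
        self.down_norms: List[Module] = []
        for _ in range(n_down):
            self.down_convs.append(Conv2d(ch, ch * 2, 3, stride=2, rng=rng))
            self.down_norms.append(InstanceNorm2d(ch * 2))
            ch *= 2
        self.res_blocks: List[Module] = [ResidualBlock(ch, rng=rng) for _ in range(n_res_blocks)]
        self.up_convs: List[Module] = []
        self.up_norms: List[Module] = []
        for _ in range(n_down):
            self.up_convs.append(Conv2d(ch, ch // 2, 3, rng=rng))
            self.up_norms.append(InstanceNorm2d(ch // 2))
            ch //= 2
        self.head = Conv2d(ch, 1, 7, rng=rng)

    # encoder tap channel counts, by tap index
    def tap_channels(self) -> List[int]:
        chans = [1, self.base_channels]
        ch = self.base_channels
        for _ in range(self.n_down):
            ch *= 2
            chans.append(ch)
        chans.append(ch)  # residual core output
        return chans

    def encode(self, x: Tensor) -> List[Tensor]:
        """Forward through the encoder, returning all tap feature maps."""
        taps = [x]
        h = self.stem_norm(self.stem(x)).relu()
        taps.append(h)
        for conv, norm in zip(self.down_convs, self.down_norms):
            h = norm(conv(h)).relu()
            taps.append(h)
        for block in self.res_blocks:
            h = block(h)
        taps.append(h)
        return taps

    def decode(self, h: Tensor) -> Tensor:
        for conv, norm in zip(self.up_convs, self.up_norms):
            h = norm(conv(upsample_nearest2x(h))).relu()
        return self.head(h).tanh()

    def __call__(self, x: Tensor) -> Tensor:
        return self.decode(self.encode(x)[-1])


class PatchDiscriminator(Module):
    """Small strided conv classifier; returns per-patch logits (pre-sigmoid)."""

    def __init__(self, base_channels: int = 16, n_layers: int = 3,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        ch = base_channels
        self.convs: List[Module] = [Conv2d(1, ch, 4, stride=2, pad=1, rng=rng)]
        self.norms: List[Optional[Module]] = [None]
        for _ in range(n_layers - 1):
            self.convs.append(Conv2d(ch, ch * 2, 4, stride=2, pad=1, rng=rng))
            self.norms.append(InstanceNorm2d(ch * 2))
            ch *= 2
        self.final = Conv2d(ch, 1, 4, stride=1, pad=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = h.leaky_relu(0.2)
        out = self.final(h)
        if out.data.size == 0:
            raise ValueError(
                f"input {x.shape[1:]} too small for a {len(self.convs)}-layer "
                "discriminator; reduce n_layers")
        return out

    @staticmethod
    def layers_for(min_spatial: int, max_layers: int = 3) -> int:
        """Deepest stride-2 stack that still leaves a nonempty patch map."""
        n = 1
        size = min_spatial // 2
        while n < max_layers and size // 2 >= 4:
            n += 1
            size //= 2
        return n


class ProjectionHead(Module):
    """Two-layer MLP mapping tap features at sampled locations to K-dim vectors."""

    def __init__(self, cin: int, k_dim: int = 256, rng: Optional[np.random.Generator] = None):
        self.fc1 = Linear(cin, k_dim, rng=rng)
        self.fc2 = Linear(k_dim, k_dim, rng=rng)

    def __call__(self, feats: Tensor) -> Tensor:
        """feats: (S, C) sampled feature vectors -> (S, K) unit vectors."""
        z = self.fc2(self.fc1(feats).relu())
        norm = ((z**2).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
        return z / norm
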