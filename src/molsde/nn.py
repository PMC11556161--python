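"""Neural-network building blocks on top of the autodiff engine.

Modules hold :class:`Parameter` leaves; parameters are discovered by
recursing attribute dictionaries in insertion order, which makes the
flattened parameter list (and therefore optimizer state, EMA shadows and
checkpoints) deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import numpy as np

from .autodiff import Tensor, concat, silu

__all__ = ["Parameter", "Module", "Linear", "MLP", "Adam", "EMA",
           "save_checkpoint", "load_checkpoint"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal parameter container with deterministic traversal order."""

    def parameters(self) -> list[Parameter]:
        return list(self._iter_parameters())

    def _iter_parameters(self) -> Iterator[Parameter]:
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                yield value
            elif isinstance(value, Module):
                yield from value._iter_parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item._iter_parameters()
                    elif isinstance(item, Parameter):
                        yield item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))
        self.n_in = n_in
        self.n_out = n_out

    def __call__(self, x: Tensor) -> Tensor:
        # flatten leading dims so the weight gradient is one large GEMM
        # instead of a stack of small batched ones
        lead = x.shape[:-1]
        if len(lead) != 1:
            x = x.reshape(-1, self.n_in)
        y = x @ self.weight + self.bias
        if len(lead) != 1:
            y = y.reshape(*lead, self.n_out)
        return y


class LayerNorm(Module):
    """Normalization over the trailing feature axis with learned gain/bias."""

    def __init__(self, dim: int, eps: float = 1e-6):
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        from .autodiff import layer_norm

        return layer_norm(x, self.gain, self.bias, self.eps)


class MLP(Module):
    """Fully connected stack with SiLU hidden activations."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 final_activation: bool = False):
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output dims")
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_activation:
                x = silu(x)
        return x


class Adam:
    """Adaptive-moment optimizer with optional global-norm gradient clipping."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = 1.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class EMA:
    """Exponential moving average of parameters (shadow weights).

    decay=0 makes the shadow track the raw weights exactly.
    """

    def __init__(self, module: Module, decay: float = 0.999):
        if not 0.0 <= decay < 1.0:
            raise ValueError("EMA decay must be in [0, 1)")
        self.module = module
        self.decay = decay
        self.shadow = module.state_arrays()

    def update(self) -> None:
        for s, p in zip(self.shadow, self.module.parameters()):
            s *= self.decay
            s += (1.0 - self.decay) * p.data

    class _Swap:
        def __init__(self, ema: "EMA"):
            self.ema = ema

        def __enter__(self):
            self.backup = self.ema.module.state_arrays()
            self.ema.module.load_state_arrays(self.ema.shadow)
            return self.ema.module

        def __exit__(self, *exc):
            self.ema.module.load_state_arrays(self.backup)
            return False

    def averaged(self) -> "EMA._Swap":
        """Context manager that temporarily loads the shadow weights."""
        return EMA._Swap(self)


def save_checkpoint(path: str | Path, module: Module, manifest: dict) -> None:
    """Write parameters as an .npz archive plus a JSON manifest sidecar."""
    path = Path(path)
    arrays = {f"p{i}": a for i, a in enumerate(module.state_arrays())}
    np.savez(path, **arrays)
    manifest_path = path.with_suffix(path.suffix + ".json")
    manifest = dict(manifest)
    manifest["n_arrays"] = len(arrays)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_checkpoint(path: str | Path, module: Module) -> dict:
    path = Path(path)
    with np.load(path) as npz:
        arrays = [npz[f"p{i}"] for i in range(len(npz.files))]
    module.load_state_arrays(arrays)
    manifest_path = path.with_suffix(path.suffix + ".json")
    if manifest_path.exists():
        return json.loads(manifest_path.read_text())
    return {}


__all__ += ["concat"]
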