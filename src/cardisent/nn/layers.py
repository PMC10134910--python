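"""Neural-network building blocks on top of the autodiff tensor.

Follows the familiar Module/Parameter idiom: modules own parameters and
buffers, expose ``train()``/``eval()`` and a flat ``state_dict`` keyed by
dotted attribute paths, and are initialized with the He normal scheme.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, avg_pool2d, batch_norm_train, conv2d

__all__ = [
    "Module",
    "Parameter",
    "Sequential",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "EvoNormProjection",
    "GaussianDropout",
    "instance_norm_stats",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -------------------------------------------------------------- traversal
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # ------------------------------------------------------------ persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({"buf::" + k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            if key.startswith("buf::"):
                name = key[5:]
                owner, attr = self._resolve(name)
                setattr(owner, attr, value.copy())
            else:
                params[key].data = value.copy().astype(np.float32)

    def _resolve(self, dotted: str):
        parts = dotted.split(".")
        obj = self
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        return obj, parts[-1]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def __getitem__(self, i):
        return self.mods[i]

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, stride=1, padding="same", bias=True, *, rng):
        super().__init__()
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(he_normal(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, fin, fout, *, rng, zero_init: bool = False):
        super().__init__()
        if zero_init:
            # near-identity start with enough scale that the conditioned
            # layers respond to the code from the first steps
            w = rng.normal(0.0, 5e-2, size=(fin, fout)).astype(np.float32)
        else:
            w = he_normal(rng, (fin, fout), fin)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(fout, dtype=np.float32))

    def forward(self, x):
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones((1, c, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, c, 1, 1), dtype=np.float32))
        self.running_mean = np.zeros((1, c, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, c, 1, 1), dtype=np.float32)

    def forward(self, x):
        if self.training:
            out, mu, var = batch_norm_train(x, self.gamma, self.beta, self.eps)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
            return out
        mu, var = Tensor(self.running_mean), Tensor(self.running_var)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma + self.beta


def instance_norm_stats(x: Tensor, eps: float = 1e-5):
    """Per-sample, per-channel mean and std over the spatial axes."""
    mu = x.mean(axis=(2, 3), keepdims=True)
    var = ((x - mu) ** 2).mean(axis=(2, 3), keepdims=True)
    return mu, (var + eps) ** 0.5


class GaussianDropout(Module):
    """Multiplicative Gaussian noise N(1, p/(1-p)); identity at evaluation."""

    def __init__(self, rate: float, *, rng):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            return x
        sigma = np.sqrt(self.rate / (1.0 - self.rate))
        noise = self.rng.normal(1.0, sigma, size=x.shape).astype(np.float32)
        return x * Tensor(noise)


class EvoNormProjection(Module):
    """Normalized 1x1 projection used in place of plain skip connections.

    The denominator pools batch-level and instance-level variance
    (sqrt(var_batch + var_inst + eps)); a learned per-channel affine
    follows, then a 1x1 convolution and multiplicative Gaussian dropout.
    No explicit activation.  Running batch variance is used at evaluation
    so the layer is deterministic in eval mode.
    """

    def __init__(self, cin, cout, *, rng, dropout=0.1, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones((1, cin, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, cin, 1, 1), dtype=np.float32))
        self.proj = Conv2d(cin, cout, k=1, rng=rng)
        self.drop = GaussianDropout(dropout, rng=rng)
        self.running_var = np.ones((1, cin, 1, 1), dtype=np.float32)

    def forward(self, x):
        if self.training:
            mu_b = x.mean(axis=(0, 2, 3), keepdims=True)
            var_b = ((x - mu_b) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var_b.data
            ).astype(np.float32)
        else:
            var_b = Tensor(self.running_var)
        mu_i = x.mean(axis=(2, 3), keepdims=True)
        var_i = ((x - mu_i) ** 2).mean(axis=(2, 3), keepdims=True)
        denom = (var_b + var_i + self.eps) ** 0.5
        xhat = (x / denom) * self.gamma + self.beta
        return self.drop(self.proj(xhat))


class ConvBlock(Module):
    """conv3x3 + BatchNorm + LeakyReLU, twice."""

    def __init__(self, cin, cout, *, rng, slope=0.2):
        super().__init__()
        self.slope = slope
        self.c1 = Conv2d(cin, cout, rng=rng)
        self.b1 = BatchNorm2d(cout)
        self.c2 = Conv2d(cout, cout, rng=rng)
        self.b2 = BatchNorm2d(cout)

    def forward(self, x):
        x = self.b1(self.c1(x)).leaky_relu(self.slope)
        return self.b2(self.c2(x)).leaky_relu(self.slope)


def downsample(x):
    return avg_pool2d(x, 2)
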