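"""Small seeded convolutional representation network.

Provides the representation function Phi mapping a grayscale stimulus image
to a flattened feature vector at any named layer, together with exact
gradients of <Phi(x), c> with respect to the input pixels.  The layer
taxonomy follows the classic AlexNet building blocks: linear convolution
(implemented as cross-correlation, no kernel flip), ReLU gating, spatial
max-pooling, and cross-channel local response normalization (LRN), plus
fully connected layers.  Weights are never trained: they are drawn once
from a zero-mean Gaussian with std 1/sqrt(fan-in) by a named, seeded
generator, so that identical (spec, seed) pairs yield bit-identical
networks.

Feature vectors are flattened channel-major, then row-major spatial
(C-order ravel of a (C, H, W) activation array).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

LAYER_TYPES = ("conv", "relu", "mpool", "norm", "fc")

__all__ = [
    "LAYER_TYPES",
    "ConfigurationError",
    "LayerSpec",
    "NetworkSpec",
    "StimulusImage",
    "FeatureVector",
    "Network",
    "build_network",
    "default_network_spec",
    "load_png",
    "save_png",
    "parse_network_config",
    "format_network_config",
]


class ConfigurationError(ValueError):
    """Raised when a network specification is internally inconsistent."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the representation network.

    Parameters
    ----------
    name : unique layer name, e.g. ``"conv1"``.
    type : one of ``conv``, ``relu``, ``mpool``, ``norm``, ``fc``.
    channels : output channels (conv) or output units (fc).
    kernel : square kernel side (conv / mpool).
    stride : spatial stride (conv / mpool).
    padding : zero padding on each side (conv / mpool).
    norm_params : ``(k, n, alpha, beta)`` of the cross-channel LRN
        ``b_c = a_c / (k + alpha * sum_{c' in window_n(c)} a_{c'}^2)^beta``.
    """

    name: str
    type: str
    channels: int | None = None
    kernel: int | None = None
    stride: int = 1
    padding: int = 0
    norm_params: tuple[float, int, float, float] = (2.0, 5, 1e-4, 0.75)

    def __post_init__(self) -> None:
        if self.type not in LAYER_TYPES:
            raise ConfigurationError(
                f"layer {self.name!r}: unknown type {self.type!r}; "
                f"must be one of {LAYER_TYPES}"
            )
        if self.type in ("conv", "fc") and (self.channels is None or self.channels < 1):
            raise ConfigurationError(f"layer {self.name!r}: positive 'channels' required")
        if self.type in ("conv", "mpool") and (self.kernel is None or self.kernel < 1):
            raise ConfigurationError(f"layer {self.name!r}: positive 'kernel' required")
        if self.stride < 1:
            raise ConfigurationError(f"layer {self.name!r}: stride must be >= 1")
        if self.padding < 0:
            raise ConfigurationError(f"layer {self.name!r}: padding must be >= 0")
        if self.type == "norm":
            k, n, alpha, beta = self.norm_params
            if n < 1 or n % 2 == 0:
                raise ConfigurationError(
                    f"layer {self.name!r}: LRN window n must be a positive odd integer"
                )


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer list plus input geometry and the weight seed."""

    layers: tuple[LayerSpec, ...]
    input_size: tuple[int, int] = (32, 32)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate layer names: {dup}")
        if not self.layers:
            raise ConfigurationError("network needs at least one layer")

    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]


@dataclass
class StimulusImage:
    """2-D grayscale image with pixel values in [0, 1]."""

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("StimulusImage pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("StimulusImage pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FeatureVector:
    """Flattened activations of one named layer.

    ``flatten_order`` records the convention: channel-major then row-major
    spatial, i.e. C-order ravel of the (C, H, W) activation array.
    """

    layer: str
    values: np.ndarray
    flatten_order: str = "channel-major"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


def _conv_out(h: int, k: int, s: int, p: int) -> int:
    return (h + 2 * p - k) // s + 1


def _chain_shapes(spec: NetworkSpec) -> dict[str, tuple[int, int, int]]:
    """Output (C, H, W) after each layer; raises naming the offending layer."""
    c, h, w = 1, spec.input_size[0], spec.input_size[1]
    shapes: dict[str, tuple[int, int, int]] = {}
    for layer in spec.layers:
        if layer.type == "conv":
            k, s, p = layer.kernel, layer.stride, layer.padding
            if k > h + 2 * p or k > w + 2 * p:
                raise ConfigurationError(
                    f"layer {layer.name!r}: kernel {k} exceeds padded input "
                    f"({h + 2 * p}x{w + 2 * p})"
                )
            h, w = _conv_out(h, k, s, p), _conv_out(w, k, s, p)
            c = layer.channels
        elif layer.type == "mpool":
            k, s, p = layer.kernel, layer.stride, layer.padding
            if k > h + 2 * p or k > w + 2 * p:
                raise ConfigurationError(
                    f"layer {layer.name!r}: pooling kernel {k} exceeds input ({h}x{w})"
                )
            h, w = _conv_out(h, k, s, p), _conv_out(w, k, s, p)
        elif layer.type == "fc":
            c, h, w = layer.channels, 1, 1
        # relu / norm keep shape
        if h < 1 or w < 1:
            raise ConfigurationError(f"layer {layer.name!r}: non-positive spatial dims")
        shapes[layer.name] = (c, h, w)
    return shapes


class Network:
    """A built (weighted) representation network.

    Construct with :func:`build_network`; weights live in ``self.weights``
    keyed by layer name and may be overwritten for controlled experiments
    (e.g. an identity representation).
    """

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        self.shapes = _chain_shapes(spec)
        self.weights: dict[str, np.ndarray] = {}
        self._init_weights()

    def _init_weights(self) -> None:
        c_in = 1
        for i, layer in enumerate(self.spec.layers):
            if layer.type == "conv":
                fan_in = c_in * layer.kernel * layer.kernel
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=self.spec.seed, spawn_key=(i,))
                )
                self.weights[layer.name] = rng.normal(
                    0.0, 1.0 / np.sqrt(fan_in),
                    size=(layer.channels, c_in, layer.kernel, layer.kernel),
                )
            elif layer.type == "fc":
                in_shape = self._input_shape(i)
                fan_in = int(np.prod(in_shape))
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=self.spec.seed, spawn_key=(i,))
                )
                self.weights[layer.name] = rng.normal(
                    0.0, 1.0 / np.sqrt(fan_in), size=(layer.channels, fan_in)
                )
            c_in = self.shapes[layer.name][0]

    def _input_shape(self, layer_index: int) -> tuple[int, int, int]:
        if layer_index == 0:
            return (1, *self.spec.input_size)
        return self.shapes[self.spec.layers[layer_index - 1].name]

    # -- public API ---------------------------------------------------------

    def layer_names(self) -> list[str]:
        return self.spec.layer_names()

    def layer_dim(self, layer: str) -> int:
        self._check_layer(layer)
        return int(np.prod(self.shapes[layer]))

    def layer_dims(self) -> dict[str, int]:
        return {name: int(np.prod(s)) for name, s in self.shapes.items()}

    def forward(self, image: StimulusImage | np.ndarray, upto_layer: str) -> FeatureVector:
        """Flattened activations of ``upto_layer`` for one image."""
        self._check_layer(upto_layer)
        acts = self._forward_acts(self._as_input(image), upto_layer)
        return FeatureVector(layer=upto_layer, values=acts[-1].ravel())

    def forward_all(self, image: StimulusImage | np.ndarray) -> dict[str, np.ndarray]:
        """Flattened activations of every layer (one shared forward pass)."""
        acts = self._forward_acts(self._as_input(image), self.spec.layers[-1].name)
        return {
            layer.name: acts[i + 1].ravel()
            for i, layer in enumerate(self.spec.layers)
        }

    def input_gradient(
        self,
        image: StimulusImage | np.ndarray,
        upto_layer: str,
        cotangent: FeatureVector | np.ndarray,
    ) -> np.ndarray:
        """Gradient of <Phi(x), cotangent> with respect to the input pixels."""
        self._check_layer(upto_layer)
        cot = cotangent.values if isinstance(cotangent, FeatureVector) else np.asarray(cotangent, float)
        d = self.layer_dim(upto_layer)
        if cot.size != d:
            raise ValueError(
                f"cotangent has {cot.size} entries but layer {upto_layer!r} has {d}"
            )
        x = self._as_input(image)
        acts = self._forward_acts(x, upto_layer)
        g = cot.reshape(self.shapes[upto_layer])
        idx = self._layer_index(upto_layer)
        for i in range(idx, -1, -1):
            layer = self.spec.layers[i]
            g = self._backward_one(layer, acts[i], g)
        return g[0]  # drop channel axis: input is (1, H, W)

    # -- internals ----------------------------------------------------------

    def _check_layer(self, layer: str) -> None:
        if layer not in self.shapes:
            raise KeyError(
                f"unknown layer {layer!r}; valid layers: {self.layer_names()}"
            )

    def _layer_index(self, layer: str) -> int:
        return self.spec.layer_names().index(layer)

    def _as_input(self, image: StimulusImage | np.ndarray) -> np.ndarray:
        px = image.pixels if isinstance(image, StimulusImage) else np.asarray(image, float)
        if px.shape != tuple(self.spec.input_size):
            raise ValueError(
                f"image shape {px.shape} does not match network input "
                f"{tuple(self.spec.input_size)}"
            )
        return px[None, :, :]

    def _forward_acts(self, x: np.ndarray, upto_layer: str) -> list[np.ndarray]:
        """[input, act_after_layer0, ..., act_after_upto_layer]."""
        acts = [x]
        for layer in self.spec.layers:
            x = self._forward_one(layer, x)
            acts.append(x)
            if layer.name == upto_layer:
                break
        return acts

    def _forward_one(self, layer: LayerSpec, x: np.ndarray) -> np.ndarray:
        if layer.type == "conv":
            return _conv_forward(x, self.weights[layer.name], layer.stride, layer.padding)
        if layer.type == "relu":
            return np.maximum(x, 0.0)
        if layer.type == "mpool":
            return _pool_forward(x, layer.kernel, layer.stride)[0]
        if layer.type == "norm":
            return _lrn_forward(x, *layer.norm_params)[0]
        if layer.type == "fc":
            w = self.weights[layer.name]
            return (w @ x.ravel()).reshape(layer.channels, 1, 1)
        raise AssertionError(layer.type)

    def _backward_one(self, layer: LayerSpec, x_in: np.ndarray, g: np.ndarray) -> np.ndarray:
        if layer.type == "conv":
            return _conv_backward(x_in.shape, self.weights[layer.name], g,
                                  layer.stride, layer.padding)
        if layer.type == "relu":
            return g * (x_in > 0)
        if layer.type == "mpool":
            _, argmax = _pool_forward(x_in, layer.kernel, layer.stride)
            return _pool_backward(x_in.shape, argmax, g, layer.kernel, layer.stride)
        if layer.type == "norm":
            return _lrn_backward(x_in, g, *layer.norm_params)
        if layer.type == "fc":
            return (self.weights[layer.name].T @ g.ravel()).reshape(x_in.shape)
        raise AssertionError(layer.type)


def build_network(spec: NetworkSpec) -> Network:
    """Build a network with seeded Gaussian weights (std 1/sqrt(fan-in))."""
    return Network(spec)


# ---------------------------------------------------------------------------
# layer primitives on (C, H, W) arrays


def _conv_forward(x: np.ndarray, w: np.ndarray, stride: int, padding: int) -> np.ndarray:
    k = w.shape[-1]
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    # win: (C_in, Ho, Wo, k, k); w: (C_out, C_in, k, k)
    return np.einsum("cijuv,ocuv->oij", win, w, optimize=True)


def _conv_backward(in_shape: tuple, w: np.ndarray, g: np.ndarray,
                   stride: int, padding: int) -> np.ndarray:
    c_in, h, wd = in_shape
    k = w.shape[-1]
    ho, wo = g.shape[1], g.shape[2]
    gp = np.zeros((c_in, h + 2 * padding, wd + 2 * padding))
    for u in range(k):
        for v in range(k):
            contrib = np.einsum("oij,oc->cij", g, w[:, :, u, v], optimize=True)
            gp[:, u:u + stride * ho:stride, v:v + stride * wo:stride] += contrib
    if padding:
        gp = gp[:, padding:-padding or None, padding:-padding or None]
    return gp


def _pool_forward(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, np.ndarray]:
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    flat = win.reshape(*win.shape[:3], k * k)
    # np.argmax returns the first maximum in C-order = row-major scan order,
    # which fixes the tie rule for the backward pass.
    argmax = np.argmax(flat, axis=-1)
    out = np.take_along_axis(flat, argmax[..., None], axis=-1)[..., 0]
    return out, argmax


def _pool_backward(in_shape: tuple, argmax: np.ndarray, g: np.ndarray,
                   k: int, stride: int) -> np.ndarray:
    c, ho, wo = g.shape
    gx = np.zeros(in_shape)
    ci, ii, jj = np.meshgrid(np.arange(c), np.arange(ho), np.arange(wo), indexing="ij")
    rows = ii * stride + argmax // k
    cols = jj * stride + argmax % k
    np.add.at(gx, (ci.ravel(), rows.ravel(), cols.ravel()), g.ravel())
    return gx


def _lrn_scale(x: np.ndarray, k0: float, n: int, alpha: float) -> np.ndarray:
    """S_c = k0 + alpha * sum over the size-n channel window of a^2."""
    sq = x * x
    half = n // 2
    c = x.shape[0]
    csum = np.cumsum(np.concatenate([np.zeros((1, *x.shape[1:])), sq], axis=0), axis=0)
    lo = np.clip(np.arange(c) - half, 0, c)
    hi = np.clip(np.arange(c) + half + 1, 0, c)
    win = csum[hi] - csum[lo]
    return k0 + alpha * win


def _lrn_forward(x: np.ndarray, k0: float, n: int, alpha: float, beta: float):
    s = _lrn_scale(x, k0, n, alpha)
    return x * s ** (-beta), s


def _lrn_backward(x: np.ndarray, g: np.ndarray, k0: float, n: int,
                  alpha: float, beta: float) -> np.ndarray:
    s = _lrn_scale(x, k0, n, alpha)
    q = g * x * s ** (-beta - 1.0)
    half = n // 2
    c = x.shape[0]
    csum = np.cumsum(np.concatenate([np.zeros((1, *x.shape[1:])), q], axis=0), axis=0)
    lo = np.clip(np.arange(c) - half, 0, c)
    hi = np.clip(np.arange(c) + half + 1, 0, c)
    win = csum[hi] - csum[lo]  # sum of q over the (symmetric) window containing c
    return g * s ** (-beta) - 2.0 * alpha * beta * x * win


# ---------------------------------------------------------------------------
# default architecture


def default_network_spec(input_size: tuple[int, int] = (32, 32), seed: int = 0) -> NetworkSpec:
    """Default 14-layer stack mirroring the AlexNet taxonomy at desk scale.

    conv1-relu1-mpool1-norm1-conv2-relu2-mpool2-norm2-conv3-relu3-conv4-
    relu4-fc5-relu5 on a 32x32 grayscale input.  mpool1 is the default
    reconstruction representation.
    """
    layers = (
        LayerSpec("conv1", "conv", channels=8, kernel=5, stride=2, padding=2),
        LayerSpec("relu1", "relu"),
        LayerSpec("mpool1", "mpool", kernel=2, stride=2),
        LayerSpec("norm1", "norm"),
        LayerSpec("conv2", "conv", channels=12, kernel=3, stride=1, padding=1),
        LayerSpec("relu2", "relu"),
        LayerSpec("mpool2", "mpool", kernel=2, stride=2),
        LayerSpec("norm2", "norm"),
        LayerSpec("conv3", "conv", channels=16, kernel=3, stride=1, padding=1),
        LayerSpec("relu3", "relu"),
        LayerSpec("conv4", "conv", channels=16, kernel=3, stride=1, padding=1),
        LayerSpec("relu4", "relu"),
        LayerSpec("fc5", "fc", channels=32),
        LayerSpec("relu5", "relu"),
    )
    return NetworkSpec(layers=layers, input_size=input_size, seed=seed)


# ---------------------------------------------------------------------------
# PNG input/output (8-bit grayscale, [0,255] <-> [0,1])


def load_png(path) -> StimulusImage:
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    return StimulusImage(pixels=arr, id=str(path))


def save_png(image: StimulusImage, path) -> None:
    from PIL import Image

    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


# ---------------------------------------------------------------------------
# plain-text configuration (key=value per layer section)


def format_network_config(spec: NetworkSpec) -> str:
    lines = ["[network]",
             f"input_size = {spec.input_size[0]}x{spec.input_size[1]}",
             f"seed = {spec.seed}", ""]
    for layer in spec.layers:
        lines.append(f"[layer:{layer.name}]")
        lines.append(f"type = {layer.type}")
        if layer.channels is not None:
            lines.append(f"channels = {layer.channels}")
        if layer.kernel is not None:
            lines.append(f"kernel = {layer.kernel}")
        if layer.type in ("conv", "mpool"):
            lines.append(f"stride = {layer.stride}")
            lines.append(f"padding = {layer.padding}")
        if layer.type == "norm":
            k0, n, a, b = layer.norm_params
            lines.append(f"norm_params = {k0},{n},{a},{b}")
        lines.append("")
    return "\n".join(lines)


def parse_network_config(text: str) -> NetworkSpec:
    import configparser

    cp = configparser.ConfigParser()
    cp.read_string(text)
    if "network" not in cp:
        raise ConfigurationError("missing [network] section")
    h, _, w = cp["network"].get("input_size", "32x32").partition("x")
    seed = cp["network"].getint("seed", 0)
    layers = []
    for section in cp.sections():
        if not section.startswith("layer:"):
            continue
        name = section.split(":", 1)[1]
        sec = cp[section]
        kwargs: dict = {"name": name, "type": sec.get("type")}
        if "channels" in sec:
            kwargs["channels"] = sec.getint("channels")
        if "kernel" in sec:
            kwargs["kernel"] = sec.getint("kernel")
        if "stride" in sec:
            kwargs["stride"] = sec.getint("stride")
        if "padding" in sec:
            kwargs["padding"] = sec.getint("padding")
        if "norm_params" in sec:
            k0, n, a, b = sec.get("norm_params").split(",")
            kwargs["norm_params"] = (float(k0), int(n), float(a), float(b))
        layers.append(LayerSpec(**kwargs))
    return NetworkSpec(layers=tuple(layers), input_size=(int(h), int(w)), seed=seed)
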