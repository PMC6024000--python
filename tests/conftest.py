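import numpy as np
import pytest

from neurorecon.network import LayerSpec, NetworkSpec, build_network


@pytest.fixture(scope="session")
def tiny_net():
    """Small network covering every layer type, on an 8x8 input."""
    spec = NetworkSpec(
        layers=(
            LayerSpec("conv1", "conv", channels=3, kernel=3, stride=1, padding=1),
            LayerSpec("relu1", "relu"),
            LayerSpec("mpool1", "mpool", kernel=2, stride=2),
            LayerSpec("norm1", "norm"),
            LayerSpec("fc2", "fc", channels=5),
        ),
        input_size=(8, 8),
        seed=1,
    )
    return build_network(spec)


@pytest.fixture(scope="session")
def identity_net():
    """Single 1x1 convolution with weight one: Phi(x) = x."""
    spec = NetworkSpec(
        layers=(LayerSpec("id", "conv", channels=1, kernel=1),),
        input_size=(16, 16),
        seed=0,
    )
    net = build_network(spec)
    net.weights["id"][:] = 1.0
    return net


@pytest.fixture(scope="session")
def pool_net():
    """conv-relu-mpool stack on 32x32 used for inversion experiments."""
    spec = NetworkSpec(
        layers=(
            LayerSpec("conv1", "conv", channels=4, kernel=5, stride=2, padding=2),
            LayerSpec("relu1", "relu"),
            LayerSpec("mpool1", "mpool", kernel=2, stride=2),
        ),
        input_size=(32, 32),
        seed=7,
    )
    return build_network(spec)


def central_fd(fun, x, h=1e-5):
    """Central finite-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += h
        xm = x.copy(); xm[idx] -= h
        g[idx] = (fun(xp) - fun(xm)) / (2 * h)
    return g
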