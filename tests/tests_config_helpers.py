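"""Shared helpers for writing miniature run configurations to disk."""

from pathlib import Path

from neurorecon.network import LayerSpec, NetworkSpec, format_network_config

TINY_PIPELINE_NET = NetworkSpec(
    layers=(
        LayerSpec("conv1", "conv", channels=4, kernel=5, stride=2, padding=2),
        LayerSpec("relu1", "relu"),
        LayerSpec("mpool1", "mpool", kernel=2, stride=2),
        LayerSpec("conv2", "conv", channels=6, kernel=3, stride=1, padding=1),
        LayerSpec("mpool2", "mpool", kernel=2, stride=2),
        LayerSpec("conv3", "conv", channels=8, kernel=3, stride=1, padding=1),
    ),
    input_size=(32, 32),
    seed=3,
)


def write_small_configs(root: Path) -> None:
    """Write a miniature YAML run config plus its network config file."""
    (root / "net.cfg").write_text(format_network_config(TINY_PIPELINE_NET))
    (root / "run.yaml").write_text(
        "\n".join(
            [
                "n_train: 20",
                "n_val: 4",
                "n_voxels: 30",
                "top_k: 8",
                "iterations: 30",
                "noise_sd: 0.3",
                "master_seed: 4",
                "layer_per_area:",
                "  V1: mpool1",
                "  V2: conv2",
                "  V3: mpool2",
                "  V4: conv3",
                f"network_config: {root / 'net.cfg'}",
                "",
            ]
        )
    )
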