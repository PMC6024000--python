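"""Synthetic stimuli and voxel responses with planted, recoverable structure.

The generator stands in for a visual-cortex encoding experiment: each voxel
responds as a sparse linear combination of the features of one network
layer, the layer being determined by the voxel's visual-area label (V1-V4),
plus Gaussian noise.  Early areas couple to shallow layers and downstream
areas to deep layers, which plants the area-to-layer-depth gradient that
the evaluation module's trend test must recover.

Also provides raw sparse-regression test problems (Gaussian design with
unit-norm columns, exactly s-sparse planted coefficients) for exercising
the sparse solvers in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .network import StimulusImage

AREAS = ("V1", "V2", "V3", "V4")

# Voxel pool sizes of the four retinotopic areas in the reference subject
# (V1:V2:V3:V4 = 1294:2083:1790:484); desk-scale panels keep the ratio.
AREA_POOL_RATIO = {"V1": 1294, "V2": 2083, "V3": 1790, "V4": 484}

IMAGE_KINDS = ("bar", "disc", "grating", "texture")

__all__ = [
    "AREAS",
    "AREA_POOL_RATIO",
    "IMAGE_KINDS",
    "EncodingGroundTruth",
    "VoxelResponseMatrix",
    "bar_image",
    "disc_image",
    "grating_image",
    "texture_image",
    "make_images",
    "make_image_split",
    "area_label_panel",
    "build_encoding_ground_truth",
    "simulate_voxels",
    "make_sparse_problem",
]


# ---------------------------------------------------------------------------
# stimulus images


def disc_image(size, center, radius, fg=1.0, bg=0.0) -> StimulusImage:
    """Filled disc; a pixel is foreground iff its center lies inside the disc."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
    px = np.full((h, w), bg, dtype=float)
    px[mask] = fg
    return StimulusImage(px, id=f"disc_r{radius:g}")


def bar_image(size, center, length, width, angle, fg=1.0, bg=0.0) -> StimulusImage:
    """Oriented rectangular bar (angle in radians, 0 = horizontal)."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - center[0], xx - center[1]
    along = dx * np.cos(angle) + dy * np.sin(angle)
    across = -dx * np.sin(angle) + dy * np.cos(angle)
    mask = (np.abs(along) <= length / 2) & (np.abs(across) <= width / 2)
    px = np.full((h, w), bg, dtype=float)
    px[mask] = fg
    return StimulusImage(px, id="bar")


def grating_image(size, frequency, angle, phase=0.0, contrast=1.0) -> StimulusImage:
    """Sinusoidal luminance grating (frequency in cycles/pixel)."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    arg = 2 * np.pi * frequency * (xx * np.cos(angle) + yy * np.sin(angle)) + phase
    px = 0.5 + 0.5 * contrast * np.sin(arg)
    return StimulusImage(px, id="grating")


def texture_image(size, smoothness, rng) -> StimulusImage:
    """Gaussian random field smoothed to the given correlation length."""
    noise = rng.standard_normal(size)
    smooth = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    px = (smooth - lo) / (hi - lo) if hi > lo else np.full(size, 0.5)
    return StimulusImage(px, id="texture")


def make_images(count: int, size=(32, 32), kinds=IMAGE_KINDS, seed: int = 0) -> list[StimulusImage]:
    """Deterministic list of grayscale stimuli of the requested kinds.

    Kinds cycle in order with randomized per-image parameters; all pixel
    values lie in [0, 1].
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    kinds = tuple(kinds)
    if not kinds:
        raise ValueError("kinds must be a non-empty set of image kinds")
    unknown = set(kinds) - set(IMAGE_KINDS)
    if unknown:
        raise ValueError(f"unknown image kinds {sorted(unknown)}; valid: {IMAGE_KINDS}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    h, w = size
    out: list[StimulusImage] = []
    for i in range(count):
        kind = kinds[i % len(kinds)]
        fg, bg = (1.0, rng.uniform(0.0, 0.3)) if rng.random() < 0.7 else (0.0, rng.uniform(0.7, 1.0))
        if kind == "disc":
            r = rng.uniform(min(h, w) / 8, min(h, w) / 3.2)
            center = (rng.uniform(r, h - r), rng.uniform(r, w - r))
            img = disc_image(size, center, r, fg, bg)
        elif kind == "bar":
            img = bar_image(
                size,
                center=(rng.uniform(h / 4, 3 * h / 4), rng.uniform(w / 4, 3 * w / 4)),
                length=rng.uniform(h / 2, h),
                width=rng.uniform(2, h / 6),
                angle=rng.uniform(0, np.pi),
                fg=fg, bg=bg,
            )
        elif kind == "grating":
            img = grating_image(
                size,
                frequency=rng.uniform(1.5 / min(h, w), 6.0 / min(h, w)),
                angle=rng.uniform(0, np.pi),
                phase=rng.uniform(0, 2 * np.pi),
                contrast=rng.uniform(0.6, 1.0),
            )
        else:
            img = texture_image(size, smoothness=rng.uniform(1.5, 4.0), rng=rng)
        img.id = f"{img.id}_{i:04d}"
        out.append(img)
    return out


def make_image_split(n_train: int = 175, n_val: int = 12, size=(32, 32),
                     kinds=IMAGE_KINDS, seed: int = 0):
    """Disjointly seeded training/validation stimulus sets.

    Defaults are the desk-scale split (one tenth of a 1750/120-image
    experiment).
    """
    train = make_images(n_train, size=size, kinds=kinds, seed=seed)
    val = make_images(n_val, size=size, kinds=kinds, seed=seed + 690001)
    for im in val:
        im.id = "val_" + im.id
    return train, val


# ---------------------------------------------------------------------------
# planted voxel encoding


@dataclass
class EncodingGroundTruth:
    """Planted sparse voxel-feature coupling.

    Voxel ``i`` (area ``area_labels[i]``) responds to the features of layer
    ``layer_per_area[area_labels[i]]`` through the sparse coupling row
    ``(supports[i], coefficients[i])``.
    """

    layer_per_area: dict[str, str]
    area_labels: list[str]
    supports: list[np.ndarray]
    coefficients: list[np.ndarray]
    noise_sd: float
    seed: int

    @property
    def n_voxels(self) -> int:
        return len(self.area_labels)

    def voxel_layer(self, i: int) -> str:
        return self.layer_per_area[self.area_labels[i]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "layer_per_area": self.layer_per_area,
                "area_labels": list(self.area_labels),
                "supports": [s.tolist() for s in self.supports],
                "coefficients": [c.tolist() for c in self.coefficients],
                "noise_sd": self.noise_sd,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EncodingGroundTruth":
        d = json.loads(text)
        return cls(
            layer_per_area=d["layer_per_area"],
            area_labels=d["area_labels"],
            supports=[np.asarray(s, dtype=int) for s in d["supports"]],
            coefficients=[np.asarray(c, dtype=float) for c in d["coefficients"]],
            noise_sd=d["noise_sd"],
            seed=d["seed"],
        )


@dataclass
class VoxelResponseMatrix:
    """Trials x voxels response array with ids and optional area labels."""

    responses: np.ndarray
    voxel_ids: list[str]
    area_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("voxel responses must be finite")
        if self.responses.shape[1] != len(self.voxel_ids):
            raise ValueError("voxel_ids length must match response columns")

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[1]


def area_label_panel(n_voxels: int = 300) -> list[str]:
    """Per-voxel area labels with counts proportional to the reference pools.

    Largest-remainder apportionment of ``AREA_POOL_RATIO`` over n_voxels;
    voxels are ordered V1 block, V2 block, V3 block, V4 block.
    """
    total = sum(AREA_POOL_RATIO.values())
    quotas = {a: n_voxels * AREA_POOL_RATIO[a] / total for a in AREAS}
    counts = {a: int(np.floor(q)) for a, q in quotas.items()}
    short = n_voxels - sum(counts.values())
    for a in sorted(AREAS, key=lambda a: quotas[a] - counts[a], reverse=True)[:short]:
        counts[a] += 1
    labels: list[str] = []
    for a in AREAS:
        labels.extend([a] * counts[a])
    return labels


DEFAULT_LAYER_PER_AREA = {"V1": "mpool1", "V2": "conv2", "V3": "mpool2", "V4": "conv4"}


def build_encoding_ground_truth(
    layer_dims: dict[str, int],
    n_voxels: int = 300,
    layer_per_area: dict[str, str] | None = None,
    s_enc: int = 3,
    noise_sd: float = 0.5,
    coef_range: tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
) -> EncodingGroundTruth:
    """Plant an s_enc-sparse coupling row per voxel onto its area's layer.

    Coupling magnitudes are uniform in ``coef_range`` with random signs.
    ``noise_sd`` is relative to each voxel's noise-free response standard
    deviation (see :func:`simulate_voxels`).
    """
    layer_per_area = dict(layer_per_area or DEFAULT_LAYER_PER_AREA)
    missing = [l for l in layer_per_area.values() if l not in layer_dims]
    if missing:
        raise ValueError(f"layers {missing} not present in layer_dims")
    if s_enc < 1:
        raise ValueError("s_enc must be >= 1")
    labels = area_label_panel(n_voxels)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    supports, coefs = [], []
    for lab in labels:
        d = layer_dims[layer_per_area[lab]]
        supp = np.sort(rng.choice(d, size=min(s_enc, d), replace=False))
        mags = rng.uniform(*coef_range, size=supp.size)
        signs = rng.choice([-1.0, 1.0], size=supp.size)
        supports.append(supp)
        coefs.append(mags * signs)
    return EncodingGroundTruth(
        layer_per_area=layer_per_area,
        area_labels=labels,
        supports=supports,
        coefficients=coefs,
        noise_sd=float(noise_sd),
        seed=seed,
    )


def simulate_voxels(
    features_per_layer: dict[str, np.ndarray],
    truth: EncodingGroundTruth,
) -> VoxelResponseMatrix:
    """Trials x voxels responses from the planted coupling plus noise.

    Each voxel's clean response is its layer's feature matrix times its
    sparse coupling row; Gaussian noise with standard deviation
    ``truth.noise_sd * sd(clean response)`` is added (absolute ``noise_sd``
    for a degenerate constant clean response).
    """
    trials = {layer: np.asarray(f).shape[0] for layer, f in features_per_layer.items()}
    if len(set(trials.values())) > 1:
        raise ValueError(f"feature matrices disagree on trial count: {trials}")
    needed = set(truth.layer_per_area.values())
    missing = needed - set(features_per_layer)
    if missing:
        raise ValueError(f"missing feature matrices for layers {sorted(missing)}")
    m = next(iter(trials.values()))
    n = truth.n_voxels
    rng = np.random.default_rng(np.random.SeedSequence(entropy=truth.seed, spawn_key=(2,)))
    resp = np.empty((m, n))
    for i in range(n):
        f = np.asarray(features_per_layer[truth.voxel_layer(i)], dtype=float)
        clean = f[:, truth.supports[i]] @ truth.coefficients[i]
        scale = clean.std()
        sd = truth.noise_sd * (scale if scale > 0 else 1.0)
        resp[:, i] = clean + rng.normal(0.0, sd, size=m) if sd > 0 else clean
    ids = [f"vox{i:04d}" for i in range(n)]
    return VoxelResponseMatrix(responses=resp, voxel_ids=ids,
                               area_labels=list(truth.area_labels))


# ---------------------------------------------------------------------------
# raw sparse-regression problems


def make_sparse_problem(m: int, n: int, s: int, noise_sd: float = 0.0, seed: int = 0):
    """Planted sparse-regression problem (X, y, w_true).

    X is i.i.d. standard Gaussian with columns normalized to unit L2 norm;
    w_true has exactly s nonzeros with magnitudes uniform in [1, 2] and
    random signs; y = X @ w_true + Gaussian(0, noise_sd) noise.
    """
    if not 1 <= s <= n:
        raise ValueError(f"sparsity s={s} must satisfy 1 <= s <= n={n}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    x = rng.standard_normal((m, n))
    x /= np.linalg.norm(x, axis=0, keepdims=True)
    w = np.zeros(n)
    supp = rng.choice(n, size=s, replace=False)
    w[supp] = rng.uniform(1.0, 2.0, size=s) * rng.choice([-1.0, 1.0], size=s)
    y = x @ w
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=m)
    return x, y, w
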