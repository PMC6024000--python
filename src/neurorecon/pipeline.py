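"""End-to-end orchestration: simulate -> extract -> fit -> predict ->
reconstruct -> evaluate, reproducibly from a single master seed.

All stage randomness is drawn from named substreams of the master seed
(`stage_seed`), so a run is bit-reproducible from its saved configuration
and partial stages can be re-run against serialized intermediates.  The
desk-scale defaults (175 training / 12 validation images, 300 voxels) are
one tenth of the reference experiment's 1750/120-image design;
``paper_scale=True`` restores the full counts (and the 5651-voxel panel
with 300 significant voxels).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decode import LayerDecoder, LayerDecoderResults
from .evaluate import (
    AccuracyReport,
    area_trends,
    cwssim,
    paired_t_test,
    prediction_accuracy,
    two_afc_identification,
    voxel_contribution,
)
from .invert import InversionConfig, reconstruct_from_predictions
from .network import (
    Network,
    NetworkSpec,
    build_network,
    default_network_spec,
    save_png,
)
from .synthdata import (
    DEFAULT_LAYER_PER_AREA,
    build_encoding_ground_truth,
    make_image_split,
    simulate_voxels,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "SimulatedStudy",
    "stage_seed",
    "prepare_study",
    "run_layer_scan",
    "run_solver_comparison",
    "run_full",
]

# Layers the solver comparison scores by default: the pooling/convolution
# representatives (ReLU layers decode poorly and fully connected layers are
# tiny, so they add little to a solver contrast).
COMPARISON_LAYERS = ("mpool1", "conv2", "mpool2", "conv3", "conv4")


def stage_seed(master_seed: int, name: str) -> int:
    """Deterministic per-stage substream seed (< 2^31) from a stage name."""
    digest = hashlib.sha256(name.encode()).digest()
    tag = int.from_bytes(digest[:4], "big")
    ss = np.random.SeedSequence(entropy=[int(master_seed), tag])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    # stimuli
    n_train: int = 175
    n_val: int = 12
    image_size: tuple[int, int] = (32, 32)
    image_kinds: tuple[str, ...] = ("bar", "disc", "grating", "texture")
    # encoding simulation
    n_voxels: int = 300
    layer_per_area: dict = field(default_factory=lambda: dict(DEFAULT_LAYER_PER_AREA))
    s_enc: int = 3
    noise_sd: float = 0.5
    # network
    network: NetworkSpec | None = None
    # decoding
    solver: str = "romp"
    sparsity: int | None = 8
    l1_lambda: float = 0.05
    # inversion
    reconstruction_layer: str = "mpool1"
    lambda_alpha: float = 1e-4
    alpha: float = 6.0
    lambda_tv: float = 1e-3
    tv_beta: float = 2.0
    step_size: float = 0.2
    momentum: float = 0.9
    iterations: int = 500
    # evaluation
    top_k: int = 60
    cwssim_levels: int = 3
    cwssim_orientations: int = 4
    # bookkeeping
    master_seed: int = 0
    output_dir: str | None = None
    paper_scale: bool = False

    def __post_init__(self) -> None:
        self.image_size = tuple(self.image_size)
        self.image_kinds = tuple(self.image_kinds)
        if self.paper_scale:
            self.n_train, self.n_val = 1750, 120
            self.n_voxels, self.top_k = 5651, 300
        if self.network is None:
            self.network = default_network_spec(
                input_size=self.image_size, seed=stage_seed(self.master_seed, "network")
            )

    def inversion_config(self) -> InversionConfig:
        return InversionConfig(
            layer=self.reconstruction_layer,
            lambda_alpha=self.lambda_alpha,
            alpha=self.alpha,
            lambda_tv=self.lambda_tv,
            tv_beta=self.tv_beta,
            step_size=self.step_size,
            momentum=self.momentum,
            iterations=self.iterations,
            seed=stage_seed(self.master_seed, "invert"),
        )

    def solver_params(self) -> dict:
        if self.solver == "romp":
            return {"s": self.sparsity} if self.sparsity else {}
        # decoding-grade L1 settings: per-feature fits need far less
        # precision than the solver's oracle-grade defaults
        return {"lam": self.l1_lambda, "tol": 1e-6, "max_iter": 800}

    def to_json_dict(self) -> dict:
        d = asdict(self)
        net = d.pop("network")
        d["network"] = {
            "input_size": list(net["input_size"]),
            "seed": net["seed"],
            "layers": [
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in layer.items() if v is not None}
                for layer in net["layers"]
            ],
        }
        return d


@dataclass
class SimulatedStudy:
    """Everything a run derives before model fitting."""

    config: RunConfig
    net: Network
    train_images: list
    val_images: list
    features_train: dict[str, np.ndarray]
    features_val: dict[str, np.ndarray]
    truth: object
    responses_train: np.ndarray
    responses_val: np.ndarray
    area_labels: list[str]


def _feature_matrices(net: Network, images) -> dict[str, np.ndarray]:
    mats: dict[str, list] = {name: [] for name in net.layer_names()}
    for im in images:
        acts = net.forward_all(im)
        for name, v in acts.items():
            mats[name].append(v)
    return {name: np.vstack(rows) for name, rows in mats.items()}


def prepare_study(cfg: RunConfig) -> SimulatedStudy:
    """Simulate stimuli, extract features, and generate voxel responses."""
    net = build_network(cfg.network)
    train, val = make_image_split(
        cfg.n_train, cfg.n_val, size=cfg.image_size, kinds=cfg.image_kinds,
        seed=stage_seed(cfg.master_seed, "images"),
    )
    f_train = _feature_matrices(net, train)
    f_val = _feature_matrices(net, val)
    truth = build_encoding_ground_truth(
        net.layer_dims(),
        n_voxels=cfg.n_voxels,
        layer_per_area=cfg.layer_per_area,
        s_enc=cfg.s_enc,
        noise_sd=cfg.noise_sd,
        seed=stage_seed(cfg.master_seed, "encoding"),
    )
    f_all = {l: np.vstack([f_train[l], f_val[l]]) for l in truth.layer_per_area.values()}
    vox = simulate_voxels(f_all, truth)
    return SimulatedStudy(
        config=cfg,
        net=net,
        train_images=train,
        val_images=val,
        features_train=f_train,
        features_val=f_val,
        truth=truth,
        responses_train=vox.responses[: cfg.n_train],
        responses_val=vox.responses[cfg.n_train:],
        area_labels=list(truth.area_labels),
    )


def _fit_layers(study: SimulatedStudy, layers, solver: str,
                solver_params: dict) -> dict[str, LayerDecoderResults]:
    out = {}
    for layer in layers:
        out[layer] = LayerDecoder(
            study.features_train[layer], study.responses_train,
            layer=layer, solver=solver, **solver_params,
        ).fit()
    return out


def _accuracy_with_null(results: LayerDecoderResults, study: SimulatedStudy,
                        n_perm: int = 200) -> tuple[AccuracyReport, float]:
    """Validation accuracy plus a row-shuffled-null p-value for its mean r."""
    layer = results.layer
    pred = results.predict(study.responses_val)
    true = study.features_val[layer]
    rep = prediction_accuracy(pred, true, layer=layer)
    tag = int.from_bytes(hashlib.sha256(layer.encode()).digest()[:4], "big")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=stage_seed(study.config.master_seed, "null"),
                               spawn_key=(tag,))
    )
    n_val = true.shape[0]
    null_means = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(n_val)
        null_means[p] = prediction_accuracy(pred[perm], true, layer=layer).mean_r
    p_val = float((1 + np.sum(null_means >= rep.mean_r)) / (1 + n_perm))
    return rep, p_val


def run_layer_scan(cfg: RunConfig, study: SimulatedStudy | None = None,
                   n_perm: int = 200):
    """Decoding accuracy of every network layer, with shuffled-null p-values.

    Returns ``(table, model_sets, study)``; the table flags the recommended
    reconstruction layer: the first max-pooling layer among high-accuracy
    layers (mean r at least the median across layers), else the argmax.
    """
    study = study or prepare_study(cfg)
    layers = study.net.layer_names()
    sets = _fit_layers(study, layers, cfg.solver, cfg.solver_params())
    rows = []
    for layer in layers:
        rep, p_null = _accuracy_with_null(sets[layer], study, n_perm=n_perm)
        rows.append({"layer": layer, "mean_r": rep.mean_r,
                     "n_features": rep.n_features, "excluded": rep.excluded,
                     "p_vs_shuffled_null": p_null})
    table = pd.DataFrame(rows)
    med = table["mean_r"].median()
    high = table[table["mean_r"] >= med]
    pools = [l for l in high["layer"]
             if study.net.spec.layers[layers.index(l)].type == "mpool"]
    recommended = pools[0] if pools else table.loc[table["mean_r"].idxmax(), "layer"]
    table["recommended"] = table["layer"] == recommended
    return table, sets, study


def run_solver_comparison(cfg: RunConfig, study: SimulatedStudy | None = None,
                          layers=COMPARISON_LAYERS):
    """ROMP vs L1 mean accuracy per layer plus a paired per-feature t-test."""
    study = study or prepare_study(cfg)
    layers = [l for l in layers if l in study.net.layer_names()]
    romp_sets = _fit_layers(study, layers, "romp",
                            {"s": cfg.sparsity} if cfg.sparsity else {})
    l1_sets = _fit_layers(study, layers, "l1",
                          {"lam": cfg.l1_lambda, "tol": 1e-6, "max_iter": 800})
    rows, r_romp_all, r_l1_all = [], [], []
    for layer in layers:
        pred_r = romp_sets[layer].predict(study.responses_val)
        pred_l = l1_sets[layer].predict(study.responses_val)
        true = study.features_val[layer]
        rep_r = prediction_accuracy(pred_r, true, layer=layer)
        rep_l = prediction_accuracy(pred_l, true, layer=layer)
        both = ~(np.isnan(rep_r.per_feature_r) | np.isnan(rep_l.per_feature_r))
        r_romp_all.append(rep_r.per_feature_r[both])
        r_l1_all.append(rep_l.per_feature_r[both])
        rows.append({"layer": layer, "mean_r_romp": rep_r.mean_r,
                     "mean_r_l1": rep_l.mean_r, "n_features": rep_r.n_features})
    ttest = paired_t_test(np.concatenate(r_romp_all), np.concatenate(r_l1_all))
    return pd.DataFrame(rows), ttest, study


@dataclass
class RunManifest:
    """Run record: config snapshot, outputs with checksums, timings."""

    config: dict
    version: str
    stages: dict[str, float]                 # stage -> seconds
    files: dict[str, str]                    # path -> sha256
    report: dict

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "version": self.version,
             "stages": self.stages, "files": self.files, "report": self.report},
            indent=2, default=float,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full(cfg: RunConfig, study: SimulatedStudy | None = None,
             n_perm: int = 200) -> RunManifest:
    """Execute every stage and assemble the final evaluation report.

    The report covers: per-layer decoding accuracy with shuffled-null
    p-values, significant-voxel area contributions with Mann-Kendall trend
    p-values across layer depth, per-trial and mean CW-SSIM of the
    reconstructions, and metric-based 2AFC identification accuracy with a
    binomial test against chance.
    """
    from scipy import stats as sps

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    study = study or prepare_study(cfg)
    timings["simulate+extract"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table, sets, _ = run_layer_scan(cfg, study=study, n_perm=n_perm)
    timings["fit+predict"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    contrib = voxel_contribution(sets, study.area_labels, top_k=cfg.top_k)
    trends = area_trends(contrib, study.net.layer_names())
    timings["contribution"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    layer = cfg.reconstruction_layer
    pred_val = sets[layer].predict(study.responses_val)
    inv_cfg = cfg.inversion_config()
    recons = reconstruct_from_predictions(study.net, pred_val, inv_cfg)
    timings["reconstruct"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    lv, ori = cfg.cwssim_levels, cfg.cwssim_orientations
    scores = [
        cwssim(orig, rec.image, levels=lv, orientations=ori)
        for orig, rec in zip(study.val_images, recons)
    ]
    rec_images = [r.image for r in recons]
    afc = two_afc_identification(
        study.val_images, rec_images,
        metric=lambda a, b: cwssim(a, b, levels=lv, orientations=ori),
        seed=stage_seed(cfg.master_seed, "afc"),
    )
    n_afc = len(rec_images)
    afc_p = float(sps.binomtest(int(round(afc * n_afc)), n_afc, 0.5,
                                alternative="greater").pvalue)
    timings["evaluate"] = time.perf_counter() - t0

    report = {
        "layer_scan": table.to_dict(orient="records"),
        "area_proportions": {
            l: contrib[l].area_proportions for l in study.net.layer_names()
        },
        "area_trends": {
            a: {"S": t.S, "z": t.z, "p": t.p_two_sided} for a, t in trends.items()
        },
        "cwssim_per_trial": scores,
        "mean_cwssim": float(np.mean(scores)),
        "two_afc_accuracy": afc,
        "two_afc_binomial_p": afc_p,
        "reconstruction_layer": layer,
        "inversion_statuses": [r.status for r in recons],
    }

    files: dict[str, str] = {}
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, (orig, rec) in enumerate(zip(study.val_images, recons)):
            p = out / f"recon_{i:03d}.png"
            save_png(rec.image, p)
            save_png(orig, out / f"original_{i:03d}.png")
        np.savetxt(out / "responses_train.tsv", study.responses_train,
                   delimiter="\t", fmt="%.6g")
        np.savetxt(out / "responses_val.tsv", study.responses_val,
                   delimiter="\t", fmt="%.6g")
        (out / "ground_truth.json").write_text(study.truth.to_json())
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        for p in sorted(out.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                files[p.name] = _sha256(p)

    manifest = RunManifest(
        config=cfg.to_json_dict(),
        version=__version__,
        stages=timings,
        files=files,
        report=report,
    )
    if cfg.output_dir:
        (Path(cfg.output_dir) / "manifest.json").write_text(manifest.to_json())
    return manifest
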