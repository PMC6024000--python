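"""Image reconstruction by regularized feature inversion.

Finds the image x* minimizing

    ||Phi(x) - Phi0||^2 / ||Phi0||^2  +  lambda_alpha * sum_i |xbar_i|^alpha
                                      +  lambda_tv * sum_i (dh_i^2 + dv_i^2)^(beta/2)

where Phi is a network layer's feature map, Phi0 the (decoded) target
features, xbar the mean-subtracted vectorized image, and dh/dv forward
pixel differences with replicate boundary.  The feature loss is normalized
by ||Phi0||^2 by default so the regularization weights are scale-free.
Optimization is gradient descent with momentum; iterates are clipped to
[0, 1] and the best iterate (lowest objective) is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import FeatureVector, Network, StimulusImage

__all__ = [
    "InversionConfig",
    "InversionResult",
    "InversionDivergence",
    "alpha_norm",
    "total_variation",
    "objective",
    "invert",
    "reconstruct_from_predictions",
]


class InversionDivergence(RuntimeError):
    """Raised when the objective blows up even after halving the step size."""


@dataclass
class InversionConfig:
    """Settings of the inversion objective and its momentum descent."""

    layer: str = "mpool1"
    lambda_alpha: float = 1e-4
    alpha: float = 6.0
    lambda_tv: float = 1e-3
    tv_beta: float = 2.0
    step_size: float = 0.2
    momentum: float = 0.9
    iterations: int = 500
    init: str = "gaussian_noise"    # or "constant"
    seed: int = 0
    loss_normalization: str = "by_target_norm"  # or "none"
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.tv_beta <= 0:
            raise ValueError("tv_beta must be > 0")
        if self.init not in ("gaussian_noise", "constant"):
            raise ValueError("init must be 'gaussian_noise' or 'constant'")
        if self.loss_normalization not in ("by_target_norm", "none"):
            raise ValueError("loss_normalization must be 'by_target_norm' or 'none'")


@dataclass
class InversionResult:
    """Best iterate of one inversion run with its loss trace."""

    image: StimulusImage
    loss_trace: np.ndarray
    feature_loss_final: float
    converged: bool
    status: str = "ok"


def alpha_norm(x: np.ndarray, alpha: float) -> tuple[float, np.ndarray]:
    """sum |xbar|^alpha of the mean-subtracted image, and its gradient."""
    xb = x - x.mean()
    a = np.abs(xb)
    value = float(np.sum(a ** alpha))
    g = alpha * np.sign(xb) * a ** (alpha - 1.0)
    g -= g.mean()  # Jacobian of the mean subtraction
    return value, g


def total_variation(x: np.ndarray, beta: float, eps: float = 1e-8) -> tuple[float, np.ndarray]:
    """sum ((dh)^2 + (dv)^2)^(beta/2) with forward differences, replicate
    boundary (last row/column differences are zero), and its gradient."""
    dh = np.zeros_like(x)
    dv = np.zeros_like(x)
    dh[:, :-1] = x[:, 1:] - x[:, :-1]
    dv[:-1, :] = x[1:, :] - x[:-1, :]
    mag2 = dh * dh + dv * dv
    if beta == 2.0:
        value = float(np.sum(mag2))
        wh, wv = 2.0 * dh, 2.0 * dv
    else:
        # eps keeps the gradient finite at zero-gradient pixels for beta < 2
        base = (mag2 + eps) ** (beta / 2.0 - 1.0)
        value = float(np.sum((mag2 + eps) ** (beta / 2.0) - eps ** (beta / 2.0)))
        wh, wv = beta * dh * base, beta * dv * base
    g = np.zeros_like(x)
    g[:, :-1] -= wh[:, :-1]
    g[:, 1:] += wh[:, :-1]
    g[:-1, :] -= wv[:-1, :]
    g[1:, :] += wv[:-1, :]
    return value, g


def objective(
    net: Network,
    x: StimulusImage | np.ndarray,
    phi0: FeatureVector | np.ndarray,
    cfg: InversionConfig,
) -> tuple[float, np.ndarray]:
    """Full inversion objective and its gradient with respect to the pixels."""
    px = x.pixels if isinstance(x, StimulusImage) else np.asarray(x, dtype=float)
    target = phi0.values if isinstance(phi0, FeatureVector) else np.asarray(phi0, float).ravel()
    d = net.layer_dim(cfg.layer)
    if target.size != d:
        raise ValueError(f"phi0 has {target.size} entries but layer "
                         f"{cfg.layer!r} has {d}")
    phi = net.forward(px, cfg.layer).values
    diff = phi - target
    norm = float(target @ target) if cfg.loss_normalization == "by_target_norm" else 1.0
    if norm == 0.0:
        norm = 1.0
    value = float(diff @ diff) / norm
    grad = net.input_gradient(px, cfg.layer, 2.0 * diff / norm)
    if cfg.lambda_alpha > 0:
        va, ga = alpha_norm(px, cfg.alpha)
        value += cfg.lambda_alpha * va
        grad = grad + cfg.lambda_alpha * ga
    if cfg.lambda_tv > 0:
        vt, gt = total_variation(px, cfg.tv_beta)
        value += cfg.lambda_tv * vt
        grad = grad + cfg.lambda_tv * gt
    return value, grad


def invert(net: Network, phi0: FeatureVector | np.ndarray, cfg: InversionConfig) -> InversionResult:
    """Momentum gradient descent on the inversion objective.

    v <- momentum * v - step * grad;  x <- clip(x + v, bounds).  The best
    iterate by objective value is tracked and returned.  If the objective
    exceeds 1e3x its initial value the step size is halved once and the
    run restarts from the initial image; a second blow-up raises
    :class:`InversionDivergence`.
    """
    target = phi0.values if isinstance(phi0, FeatureVector) else np.asarray(phi0, float).ravel()
    h, w = net.spec.input_size
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(4,)))
    if cfg.init == "gaussian_noise":
        x0 = np.clip(0.5 + 0.15 * rng.standard_normal((h, w)), *cfg.bounds)
    else:
        x0 = np.full((h, w), 0.5)

    step = cfg.step_size
    halved = False
    while True:
        x = x0.copy()
        v = np.zeros_like(x)
        val, grad = objective(net, x, target, cfg)
        val0 = val
        trace: list[float] = [val]
        best_val, best_x = val, x.copy()
        diverged = False
        for _ in range(cfg.iterations):
            if not np.isfinite(val) or val > 1e3 * max(val0, 1e-12):
                diverged = True
                break
            v = cfg.momentum * v - step * grad
            x = np.clip(x + v, *cfg.bounds)
            val, grad = objective(net, x, target, cfg)
            trace.append(val)
            if val < best_val:
                best_val, best_x = val, x.copy()
        if not diverged:
            break
        if halved or not np.isfinite(val):
            raise InversionDivergence(
                f"objective diverged ({val:.3g} vs initial {val0:.3g}; "
                f"step size {step:.3g})"
            )
        step *= 0.5
        halved = True

    phi_best = net.forward(best_x, cfg.layer).values
    norm = float(target @ target) if cfg.loss_normalization == "by_target_norm" else 1.0
    if norm == 0.0:
        norm = 1.0
    feat_loss = float(np.sum((phi_best - target) ** 2)) / norm
    return InversionResult(
        image=StimulusImage(best_x, id=f"recon_{cfg.layer}"),
        loss_trace=np.asarray(trace),
        feature_loss_final=feat_loss,
        converged=bool(best_val <= val0),
    )


def reconstruct_from_predictions(
    net: Network,
    predicted: np.ndarray,
    cfg: InversionConfig,
) -> list[InversionResult]:
    """Independent inversion of each predicted-feature row.

    Per-trial seeds are derived from ``cfg.seed``; a failing trial is
    reported through its result's ``status`` (the batch never aborts).
    """
    pred = np.atleast_2d(np.asarray(predicted, dtype=float))
    d = net.layer_dim(cfg.layer)
    if pred.shape[1] != d:
        raise ValueError(f"predictions have {pred.shape[1]} columns but layer "
                         f"{cfg.layer!r} has {d}")
    results: list[InversionResult] = []
    for t, row in enumerate(pred):
        cfg_t = replace(cfg, seed=int((cfg.seed * 100003 + t) % 2**31))
        try:
            results.append(invert(net, row, cfg_t))
        except Exception as exc:  # per-trial isolation
            h, w = net.spec.input_size
            results.append(
                InversionResult(
                    image=StimulusImage(np.full((h, w), 0.5), id=f"failed_{t}"),
                    loss_trace=np.array([np.inf]),
                    feature_loss_final=np.inf,
                    converged=False,
                    status=f"error: {exc}",
                )
            )
    return results
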