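"""Sparse linear decoding of voxel responses into network features.

For each scalar feature f of a network layer, a sparse linear model

    y = X w        (X: trials x (voxels + 1), last column constant one)

is fitted from the voxel-response matrix, either by regularized orthogonal
matching pursuit (ROMP) or by L1 basis pursuit (equality-constrained, via
a penalized homotopy) / the penalized Lasso program

    min_w  0.5 ||X w - y||^2 + lambda ||w||_1 .

Voxel columns are z-scored with training-set statistics before fitting and
the intercept is fitted through the appended constant column, never counted
toward the sparsity budget.

The model-fitting interface follows the Model -> fit() -> Results idiom:
``LayerDecoder(features, responses).fit()`` returns
:class:`LayerDecoderResults` holding one :class:`SparseLinearModel` per
feature, shared standardization statistics, prediction, and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SparseLinearModel",
    "fit_romp",
    "fit_l1",
    "default_sparsity",
    "LayerDecoder",
    "LayerDecoderResults",
    "fit_layer_decoders",
    "predict",
]

# Entries with |w| below this fraction of max|w| are treated as exact zeros
# when defining the support of an L1 solution (iterative solvers produce
# near-zeros, not zeros).
L1_SUPPORT_TRUNCATION = 1e-6

# After ROMP terminates, support entries whose refit coefficient is below
# this fraction of the largest are pruned (ROMP guarantees recovery of a
# superset of the true support; the least-squares refit zeroes the excess).
ROMP_PRUNE_TOL = 1e-8


@dataclass
class SparseLinearModel:
    """Sparse weight vector with intercept (last entry) and explicit support."""

    weights: np.ndarray          # length n+1, intercept last
    support: np.ndarray          # sorted voxel indices with nonzero weight
    solver: str
    n_iter: int = 0
    residual_norm: float = 0.0
    converged: bool = True
    flagged: bool = False        # degenerate target (e.g. constant feature)

    @property
    def intercept(self) -> float:
        return float(self.weights[-1])

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x @ self.weights[:-1] + self.weights[-1]


def default_sparsity(m: int, n: int, cap: int = 50) -> int:
    """ceil(m / (2 log n)) capped — the m ~ s log n compressed-sensing rule."""
    if n < 2:
        return 1
    return int(min(cap, max(1, np.ceil(m / (2.0 * np.log(n))))))


def _ls_refit(x: np.ndarray, y: np.ndarray, support: np.ndarray):
    """Least squares on the supported columns plus an intercept."""
    m = x.shape[0]
    a = np.column_stack([x[:, support], np.ones(m)])
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - a @ coef
    return coef, resid


def _regularized_subset(u_abs: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Max-energy subset of the candidates with comparable magnitudes.

    Candidates come sorted descending by |u|.  A subset is 'comparable' when
    max <= 2 * min; an optimal comparable subset is contiguous in sorted
    order, so a two-pointer sweep over windows suffices.  Ties break toward
    the earliest window start (hence, via the sort, toward lower indices).
    """
    vals = u_abs[order]
    k = len(vals)
    energy = np.concatenate([[0.0], np.cumsum(vals ** 2)])
    best_e, best = -1.0, slice(0, 1)
    j = 0
    for i in range(k):
        if j < i + 1:
            j = i + 1
        while j < k and vals[j] >= vals[i] / 2.0:
            j += 1
        e = energy[j] - energy[i]
        if e > best_e + 1e-15:
            best_e, best = e, slice(i, j)
    return order[best]


def fit_romp(
    x: np.ndarray,
    y: np.ndarray,
    s: int | None = None,
    max_support: int | None = None,
    res_tol: float | None = None,
) -> SparseLinearModel:
    """Regularized orthogonal matching pursuit with least-squares refitting.

    Per iteration: correlate the residual with all columns, take the s
    largest nonzero |correlations| (excluding already-selected columns),
    keep the maximum-energy subset with comparable magnitudes
    (max <= 2 min), add it to the support, refit least squares (with
    intercept) on the support, update the residual.  Stops when the support
    reaches ``max_support`` (default 2 s) or the residual norm falls below
    ``res_tol`` (default 1e-10 ||y||).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("fit_romp requires finite inputs")
    m, n = x.shape
    if y.size != m:
        raise ValueError(f"y has length {y.size}, expected {m}")
    if np.all(y == 0):
        return SparseLinearModel(np.zeros(n + 1), np.empty(0, dtype=int), "romp")
    if s is None:
        s = default_sparsity(m, n)
    if s < 1:
        raise ValueError("sparsity s must be >= 1")
    if max_support is None:
        max_support = 2 * s
    ynorm = np.linalg.norm(y)
    if res_tol is None:
        res_tol = 1e-10 * ynorm

    support: np.ndarray = np.empty(0, dtype=int)
    resid = y - y.mean()  # intercept-only start
    n_iter = 0
    while len(support) < max_support and np.linalg.norm(resid) > res_tol:
        u = x.T @ resid
        u_abs = np.abs(u)
        if len(support):
            u_abs[support] = 0.0
        cand = np.flatnonzero(u_abs > 0)
        if cand.size == 0:
            break
        # stable sort => ties resolved toward the lowest index
        order = cand[np.argsort(-u_abs[cand], kind="stable")][:s]
        chosen = _regularized_subset(u_abs, order)
        room = max_support - len(support)
        if chosen.size > room:
            chosen = chosen[:room]
        support = np.sort(np.concatenate([support, chosen]))
        coef, resid = _ls_refit(x, y, support)
        n_iter += 1

    if len(support) == 0:
        w = np.zeros(n + 1)
        w[-1] = y.mean()
        return SparseLinearModel(w, support, "romp", n_iter,
                                 float(np.linalg.norm(y - y.mean())))

    coef, resid = _ls_refit(x, y, support)
    keep = np.abs(coef[:-1]) > ROMP_PRUNE_TOL * np.max(np.abs(coef[:-1]))
    if not np.all(keep):
        support = support[keep]
        if len(support):
            coef, resid = _ls_refit(x, y, support)
        else:
            coef = np.array([y.mean()])
            resid = y - y.mean()
    w = np.zeros(n + 1)
    if len(support):
        w[support] = coef[:-1]
    w[-1] = coef[-1]
    return SparseLinearModel(w, support, "romp", n_iter, float(np.linalg.norm(resid)))


# ---------------------------------------------------------------------------
# L1 basis pursuit / Lasso


def _lasso_objective(x, y, w, lam):
    r = x @ w - y
    return 0.5 * r @ r + lam * np.abs(w).sum()


def _soft(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _mfista(x, y, lam, w0, tol, max_iter):
    """Monotone FISTA for 0.5||Xw-y||^2 + lam||w||_1.

    The kept iterate never increases the objective (the accelerated
    candidate is discarded when it would), so the recorded objective trace
    is non-increasing.
    """
    m, n = x.shape
    # Lipschitz constant of the smooth part = ||X||_2^2 (power iteration)
    v = np.ones(n) / np.sqrt(n)
    for _ in range(60):
        v = x.T @ (x @ v)
        nv = np.linalg.norm(v)
        if nv == 0:
            break
        v /= nv
    lip = max(nv, 1e-12)
    step = 1.0 / lip

    w = w0.copy()
    z = w.copy()
    t = 1.0
    obj = _lasso_objective(x, y, w, lam)
    trace = [obj]
    converged = False
    for it in range(max_iter):
        grad = x.T @ (x @ z - y)
        cand = _soft(z - step * grad, step * lam)
        obj_cand = _lasso_objective(x, y, cand, lam)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        accepted = obj_cand <= obj
        if accepted:
            w_next, obj_next = cand, obj_cand
        else:  # monotone safeguard: keep w, restart momentum from it
            w_next, obj_next = w, obj
        z = w_next + (t / t_next) * (cand - w_next) + ((t - 1.0) / t_next) * (w_next - w)
        step_change = np.max(np.abs(cand - z)) if not accepted else np.max(np.abs(w_next - w))
        if step_change <= tol * max(1.0, np.max(np.abs(w_next))) and it > 0:
            w, obj = w_next, obj_next
            trace.append(obj)
            converged = True
            break
        t = t_next
        w, obj = w_next, obj_next
        trace.append(obj)
    return w, np.asarray(trace), converged, len(trace) - 1


def fit_l1(
    x: np.ndarray,
    y: np.ndarray,
    mode: str = "penalized",
    lam: float = 0.1,
    tol: float = 1e-10,
    max_iter: int = 2000,
    fit_intercept: bool = True,
) -> SparseLinearModel:
    """L1 sparse recovery.

    ``mode="penalized"`` solves min 0.5||Xw-y||^2 + lam||w||_1 by monotone
    FISTA.  ``mode="equality"`` approximates basis pursuit
    (min ||w||_1 s.t. Xw = y) by a warm-started homotopy over a decreasing
    lambda sequence ending at 1e-8 ||X^T y||_inf.  The intercept is fitted
    by centering and is never penalized.  Entries below
    ``L1_SUPPORT_TRUNCATION * max|w|`` are zeroed to define the support.
    A model that hits ``max_iter`` without meeting ``tol`` is returned with
    ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("fit_l1 requires finite inputs")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if mode not in ("penalized", "equality"):
        raise ValueError("mode must be 'penalized' or 'equality'")
    m, n = x.shape
    if np.all(y == 0):
        return SparseLinearModel(np.zeros(n + 1), np.empty(0, dtype=int), "l1")

    if fit_intercept:
        x_mean = x.mean(axis=0)
        y_mean = y.mean()
        xc = x - x_mean
        yc = y - y_mean
    else:
        x_mean = np.zeros(n)
        y_mean = 0.0
        xc, yc = x, y

    if mode == "penalized":
        w, trace, converged, n_iter = _mfista(xc, yc, lam, np.zeros(n), tol, max_iter)
    else:
        lam_max = np.max(np.abs(xc.T @ yc))
        lams = lam_max * np.geomspace(0.5, 1e-8, 12)
        w = np.zeros(n)
        n_iter = 0
        converged = True
        per_stage = max(50, max_iter // len(lams))
        for lk in lams:
            w, trace, conv_k, it_k = _mfista(xc, yc, lk, w, tol, per_stage)
            n_iter += it_k
        converged = conv_k

    wmax = np.max(np.abs(w)) if w.size else 0.0
    if wmax > 0:
        w[np.abs(w) <= L1_SUPPORT_TRUNCATION * wmax] = 0.0
    support = np.flatnonzero(w)
    full = np.zeros(n + 1)
    full[:n] = w
    full[-1] = y_mean - x_mean @ w
    resid = y - (x @ w + full[-1])
    return SparseLinearModel(full, support, "l1", n_iter,
                             float(np.linalg.norm(resid)), converged=converged)


# ---------------------------------------------------------------------------
# per-layer decoding model (Model -> fit() -> Results)


@dataclass
class TrainStats:
    """Per-voxel standardization statistics from the training set."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


class LayerDecoder:
    """Sparse voxel-to-feature decoding model for one network layer.

    Parameters
    ----------
    features : (trials, D) feature matrix of the layer (the regression
        targets, one model per column).
    responses : (trials, n_voxels) voxel-response matrix (the design).
    layer : layer name, carried through to reports.
    solver : ``"romp"`` or ``"l1"``.
    solver_params : forwarded to :func:`fit_romp` / :func:`fit_l1`.
    """

    def __init__(self, features, responses, layer: str = "layer",
                 solver: str = "romp", **solver_params):
        self.features = np.asarray(features, dtype=float)
        self.responses = np.asarray(responses, dtype=float)
        if self.features.ndim == 1:
            self.features = self.features[:, None]
        if self.features.shape[0] != self.responses.shape[0]:
            raise ValueError(
                f"features have {self.features.shape[0]} trials but responses "
                f"have {self.responses.shape[0]}"
            )
        if solver not in ("romp", "l1"):
            raise ValueError("solver must be 'romp' or 'l1'")
        self.layer = layer
        self.solver = solver
        self.solver_params = solver_params

    def fit(self) -> "LayerDecoderResults":
        mean = self.responses.mean(axis=0)
        sd = self.responses.std(axis=0)
        stats = TrainStats(mean=mean, sd=np.where(sd > 0, sd, 1.0))
        z = stats.transform(self.responses)
        n = z.shape[1]
        fitter = fit_romp if self.solver == "romp" else fit_l1
        models: list[SparseLinearModel] = []
        for j in range(self.features.shape[1]):
            f = self.features[:, j]
            if np.ptp(f) == 0:  # constant feature: skipped and flagged
                w = np.zeros(n + 1)
                w[-1] = f[0] if f.size else 0.0
                models.append(SparseLinearModel(w, np.empty(0, dtype=int),
                                                self.solver, flagged=True))
                continue
            models.append(fitter(z, f, **self.solver_params))
        return LayerDecoderResults(layer=self.layer, solver=self.solver,
                                   models=models, train_stats=stats)


@dataclass
class LayerDecoderResults:
    """Fitted per-feature sparse models sharing standardization statistics."""

    layer: str
    solver: str
    models: list[SparseLinearModel]
    train_stats: TrainStats

    @property
    def n_features(self) -> int:
        return len(self.models)

    @property
    def n_voxels(self) -> int:
        return len(self.train_stats.mean)

    @property
    def excluded(self) -> np.ndarray:
        """Indices of degenerate (flagged) features."""
        return np.array([j for j, m in enumerate(self.models) if m.flagged], dtype=int)

    def weight_matrix(self) -> np.ndarray:
        """(n_voxels + 1, D) stacked weights, intercept in the last row."""
        return np.column_stack([m.weights for m in self.models])

    def predict(self, responses_new: np.ndarray) -> np.ndarray:
        """Predicted (trials, D) features for new voxel responses."""
        x = np.asarray(responses_new, dtype=float)
        if x.shape[1] != self.n_voxels:
            raise ValueError(
                f"responses have {x.shape[1]} voxels, model was fitted on "
                f"{self.n_voxels}"
            )
        z = self.train_stats.transform(x)
        za = np.column_stack([z, np.ones(z.shape[0])])
        return za @ self.weight_matrix()

    def voxel_frequencies(self) -> np.ndarray:
        """Per-voxel count of features whose support contains the voxel."""
        freq = np.zeros(self.n_voxels, dtype=int)
        for m in self.models:
            freq[m.support] += 1
        return freq

    def voxel_weight_mass(self) -> np.ndarray:
        """Per-voxel sum of |weights| across feature models (tie-break key)."""
        mass = np.zeros(self.n_voxels)
        for m in self.models:
            mass[m.support] += np.abs(m.weights[m.support])
        return mass

    def summary(self) -> pd.DataFrame:
        sizes = [len(m.support) for m in self.models if not m.flagged]
        resid = [m.residual_norm for m in self.models if not m.flagged]
        return pd.DataFrame(
            {
                "layer": [self.layer],
                "solver": [self.solver],
                "n_features": [self.n_features],
                "n_excluded": [len(self.excluded)],
                "n_voxels": [self.n_voxels],
                "mean_support": [float(np.mean(sizes)) if sizes else 0.0],
                "mean_residual_norm": [float(np.mean(resid)) if resid else 0.0],
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "layer": self.layer,
            "solver": self.solver,
            "train_mean": self.train_stats.mean.tolist(),
            "train_sd": self.train_stats.sd.tolist(),
            "models": [
                {
                    "support": m.support.tolist(),
                    "values": m.weights[m.support].tolist(),
                    "intercept": m.intercept,
                    "flagged": m.flagged,
                    "residual_norm": m.residual_norm,
                    "converged": m.converged,
                }
                for m in self.models
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "LayerDecoderResults":
        stats = TrainStats(np.asarray(d["train_mean"], float),
                           np.asarray(d["train_sd"], float))
        n = len(d["train_mean"])
        models = []
        for md in d["models"]:
            w = np.zeros(n + 1)
            supp = np.asarray(md["support"], dtype=int)
            w[supp] = md["values"]
            w[-1] = md["intercept"]
            models.append(SparseLinearModel(w, supp, d["solver"],
                                            residual_norm=md["residual_norm"],
                                            converged=md["converged"],
                                            flagged=md["flagged"]))
        return cls(layer=d["layer"], solver=d["solver"], models=models,
                   train_stats=stats)


def fit_layer_decoders(responses, features, solver: str = "romp",
                       layer: str = "layer", **solver_params) -> LayerDecoderResults:
    """Functional wrapper: fit one sparse model per feature column."""
    return LayerDecoder(features, responses, layer=layer, solver=solver,
                        **solver_params).fit()


def predict(results: LayerDecoderResults, responses_new) -> np.ndarray:
    """Functional wrapper around :meth:`LayerDecoderResults.predict`."""
    return results.predict(responses_new)
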